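"""Targeted peak extraction and intensity-matrix construction.

Each sample arrives as a flat peak list (m/z, retention time, intensity)
from centroided full-scan acquisition.  Quantification is library-driven:
for every catalogue species we look for peaks within a relative mass
tolerance (ppm) of the adduct m/z and within a retention-time window of
the expected RT, and take the most intense candidate.  Rows of the
resulting samples x species matrix are then normalised to their total ion
count (TIC) over the matched species so that samples of different overall
signal are comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .library import LipidLibrary, LipidSpecies

__all__ = [
    "PeakList",
    "IntensityMatrix",
    "ppm_error",
    "extract_intensity",
    "build_matrix",
    "tic_normalize",
    "DEFAULT_PPM_TOL",
    "DEFAULT_RT_WINDOW",
]

logger = logging.getLogger(__name__)

#: Default mass tolerance (ppm) for library matching.
DEFAULT_PPM_TOL = 5.0
#: Default retention-time window (minutes), a typical UPLC peak half-width.
DEFAULT_RT_WINDOW = 0.2


@dataclass
class PeakList:
    """Centroided peaks of one sample: columns (mz Da, rt min, intensity)."""

    sample_id: str
    peaks: np.ndarray  # shape (n, 3)

    def __post_init__(self) -> None:
        arr = np.asarray(self.peaks, dtype=float)
        if arr.size == 0:
            arr = arr.reshape(0, 3)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValueError(f"{self.sample_id}: peaks must be (n, 3) mz/rt/intensity")
        if (arr[:, 0] <= 0).any():
            raise ValueError(f"{self.sample_id}: all m/z values must be positive")
        if (arr[:, 1] < 0).any():
            raise ValueError(f"{self.sample_id}: retention times must be >= 0")
        if (arr[:, 2] < 0).any():
            raise ValueError(f"{self.sample_id}: intensities must be >= 0")
        self.peaks = arr

    def __len__(self) -> int:
        return self.peaks.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "mz": self.peaks[:, 0],
                "rt": self.peaks[:, 1],
                "intensity": self.peaks[:, 2],
            }
        )


@dataclass
class IntensityMatrix:
    """Samples x species quantification table (columns in library order)."""

    sample_ids: list[str]
    species_names: list[str]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.species_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.species_names)} species"
            )
        if (self.values < 0).any():
            raise ValueError("intensities must be non-negative")
        if self.normalized:
            sums = self.values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError("normalized matrix rows must sum to 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_ids.index(sample_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.species_names)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"#normalized={'true' if self.normalized else 'false'}\n")
            self.to_dataframe().rename_axis("sample_id").to_csv(fh, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntensityMatrix":
        path = Path(path)
        normalized = False
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
            if first.startswith("#normalized="):
                normalized = first.strip().split("=", 1)[1].lower() == "true"
            else:
                fh.seek(0)
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        return cls(
            sample_ids=[str(s) for s in frame.index],
            species_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            normalized=normalized,
        )

    def drop_all_zero_species(self) -> "IntensityMatrix":
        """Drop species that are zero in every sample (they carry no variance
        and break unit-variance scaling downstream)."""
        keep = self.values.sum(axis=0) > 0
        dropped = [n for n, k in zip(self.species_names, keep) if not k]
        if dropped:
            logger.warning("dropping %d all-zero species: %s", len(dropped), dropped[:10])
        return IntensityMatrix(
            sample_ids=list(self.sample_ids),
            species_names=[n for n, k in zip(self.species_names, keep) if k],
            values=self.values[:, keep],
            # row sums are unchanged (dropped columns were all zero)
            normalized=self.normalized,
        )


def ppm_error(observed_mz: float, reference_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if not reference_mz > 0:
        raise ValueError(f"reference m/z must be positive, got {reference_mz}")
    return (observed_mz - reference_mz) / reference_mz * 1e6


def extract_intensity(
    peaklist: PeakList,
    species: LipidSpecies,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_window: float = DEFAULT_RT_WINDOW,
    agg: str = "max",
) -> float:
    """Intensity of one library species in one sample.

    Candidates are peaks with ``|ppm_error| <= ppm_tol`` relative to the
    species' adduct m/z and ``|rt - expected_rt| <= rt_window``.  With
    ``agg='max'`` (default) the most intense candidate wins — robust to
    noise shoulders; ``agg='sum'`` totals all candidates.  Absence is
    reported as 0, not an error.
    """
    if not ppm_tol > 0:
        raise ValueError("ppm_tol must be positive")
    if not rt_window > 0:
        raise ValueError("rt_window must be positive")
    if agg not in ("max", "sum"):
        raise ValueError(f"unknown aggregation {agg!r} (use 'max' or 'sum')")
    if len(peaklist) == 0:
        return 0.0
    target_mz = species.mz
    mz, rt, inten = peaklist.peaks.T
    in_mass = np.abs((mz - target_mz) / target_mz * 1e6) <= ppm_tol
    in_rt = np.abs(rt - species.expected_rt) <= rt_window
    candidates = inten[in_mass & in_rt]
    if candidates.size == 0:
        return 0.0
    return float(candidates.max() if agg == "max" else candidates.sum())


def build_matrix(
    peaklists: Sequence[PeakList],
    library: LipidLibrary,
    ppm_tol: float = DEFAULT_PPM_TOL,
    rt_window: float = DEFAULT_RT_WINDOW,
    agg: str = "max",
) -> IntensityMatrix:
    """Quantify every library species in every sample (raw, unnormalised).

    Column order is the library order; row order is the input sample order.
    """
    if len(peaklists) == 0:
        raise ValueError("at least one peak list is required")
    ids = [pl.sample_id for pl in peaklists]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample_ids: {sorted(dupes)}")
    values = np.zeros((len(peaklists), len(library)))
    for i, pl in enumerate(peaklists):
        for j, sp in enumerate(library):
            values[i, j] = extract_intensity(pl, sp, ppm_tol, rt_window, agg)
        n_missing = int((values[i] == 0).sum())
        logger.info(
            "sample %s: matched %d/%d species (%d missing)",
            pl.sample_id, len(library) - n_missing, len(library), n_missing,
        )
    return IntensityMatrix(
        sample_ids=ids, species_names=library.names, values=values, normalized=False
    )


def tic_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample row by its total ion count over matched species.

    The resulting rows sum to 1, making samples of different absolute
    signal comparable.  Idempotent; raises on an all-zero sample row.
    """
    sums = matrix.values.sum(axis=1)
    zero = [sid for sid, s in zip(matrix.sample_ids, sums) if s <= 0]
    if zero:
        raise ValueError(f"cannot TIC-normalize all-zero sample row(s): {zero}")
    return IntensityMatrix(
        sample_ids=list(matrix.sample_ids),
        species_names=list(matrix.species_names),
        values=matrix.values / sums[:, None],
        normalized=True,
    )
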