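"""Readers and writers for the pipeline's plain-text interchange formats.

Peak lists travel as CSV (``sample_id,mz,rt,intensity``; one file may
hold several samples), cohort metadata as CSV
(``sample_id,ls_ratio,lbc,gw,flm_outcome``), intensity matrices as TSV
with a ``#normalized=`` comment line (see
:meth:`~amnioscan.extraction.IntensityMatrix.to_tsv`), and pathways as
JSON (see :mod:`amnioscan.pathway`).  Centroided MS1 mzML is supported
through pyteomics as an alternative peak-list source.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .diagnostics import SampleRecord
from .extraction import PeakList

__all__ = [
    "read_peaklists_csv",
    "write_peaklists_csv",
    "read_peaklist_mzml",
    "read_cohort_csv",
    "write_cohort_csv",
]

_PEAK_COLUMNS = ["sample_id", "mz", "rt", "intensity"]


def read_peaklists_csv(path: str | Path) -> list[PeakList]:
    """Read one or more samples' peak lists from a single CSV."""
    frame = pd.read_csv(path, comment="#")
    missing = [c for c in _PEAK_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for sid, grp in frame.groupby("sample_id", sort=False):
        out.append(
            PeakList(
                sample_id=str(sid),
                peaks=grp[["mz", "rt", "intensity"]].to_numpy(dtype=float),
            )
        )
    return out


def write_peaklists_csv(peaklists: Sequence[PeakList], path: str | Path) -> None:
    pd.concat([pl.to_dataframe() for pl in peaklists], ignore_index=True).to_csv(
        path, index=False
    )


def read_peaklist_mzml(path: str | Path, sample_id: Optional[str] = None) -> PeakList:
    """Read centroided MS1 spectra from mzML into a flat peak list.

    Scan start times are converted to minutes.  MS levels other than 1
    are skipped.
    """
    from pyteomics import mzml as _mzml

    path = Path(path)
    rows = []
    with _mzml.MzML(str(path)) as reader:
        for spectrum in reader:
            if int(spectrum.get("ms level", 1)) != 1:
                continue
            scan = spectrum["scanList"]["scan"][0]
            rt = scan["scan start time"]
            minutes = float(rt)
            unit = getattr(rt, "unit_info", "minute")
            if unit and "second" in str(unit):
                minutes /= 60.0
            mz = np.asarray(spectrum["m/z array"], dtype=float)
            inten = np.asarray(spectrum["intensity array"], dtype=float)
            rows.append(np.column_stack([mz, np.full_like(mz, minutes), inten]))
    peaks = np.vstack(rows) if rows else np.empty((0, 3))
    return PeakList(sample_id=sample_id or path.stem, peaks=peaks)


def read_cohort_csv(path: str | Path) -> list[SampleRecord]:
    """Read cohort metadata (``sample_id,ls_ratio,lbc,gw,flm_outcome``).

    ``flm_outcome`` takes ``premature``, ``mature`` or ``control_18gw``;
    empty ``ls_ratio``/``lbc`` cells mean the measurement is absent.
    """
    frame = pd.read_csv(path, comment="#")
    required = ["sample_id", "gw", "flm_outcome"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for row in frame.to_dict("records"):
        outcome = str(row["flm_outcome"])
        is_ctrl = outcome == "control_18gw"
        ls = row.get("ls_ratio")
        lbc = row.get("lbc")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                gw=int(row["gw"]),
                group="control_18gw" if is_ctrl else outcome,
                flm_outcome="unknown" if is_ctrl else outcome,
                ls_ratio=None if ls is None or pd.isna(ls) else float(ls),
                lbc=None if lbc is None or pd.isna(lbc) else float(lbc),
            )
        )
    return records


def write_cohort_csv(records: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "ls_ratio": r.ls_ratio,
                "lbc": r.lbc,
                "gw": r.gw,
                "flm_outcome": "control_18gw" if r.group == "control_18gw" else r.flm_outcome,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
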