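"""Fetal lung maturity (FLM) classifiers and their clinical evaluation.

Two bedside-relevant predictors of surfactant sufficiency in amniotic
fluid are implemented:

* the lecithin/sphingomyelin (L/S) ratio — summed intensity of the diacyl
  PC (lecithin) panel divided by summed sphingomyelin intensity, compared
  against a cutoff of 10.0 for the summed-intensity mass-spectrometry
  variant of the assay;
* the lamellar body count (LBC) from a haematology analyser's platelet
  channel, compared against 50 x 10^9/L.

Premature is the positive class (it is the condition being screened), so
sensitivity is the fraction of premature-outcome samples flagged
premature and specificity the fraction of mature-outcome samples flagged
mature.  Values exactly at a cutoff classify as mature (the partition is
"ratio < cutoff" vs the rest).  Mid-trimester (18 gestational weeks)
amniocentesis samples count as premature outcomes during evaluation: at
18 GW the fetal lung cannot be mature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .extraction import IntensityMatrix
from .library import LipidLibrary

__all__ = [
    "SampleRecord",
    "ConfusionSummary",
    "ls_ratio",
    "ls_ratios",
    "classify_ls",
    "classify_lbc",
    "evaluate",
    "DEFAULT_LS_CUTOFF",
    "DEFAULT_LBC_CUTOFF",
]

DEFAULT_LS_CUTOFF = 10.0
DEFAULT_LBC_CUTOFF = 50.0

GROUPS = ("control_18gw", "premature", "mature")
OUTCOMES = ("premature", "mature", "unknown")


@dataclass
class SampleRecord:
    """Clinical metadata for one amniotic-fluid sample."""

    sample_id: str
    gw: int
    group: str
    flm_outcome: str = "unknown"
    lbc: Optional[float] = None
    ls_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not (10 <= self.gw <= 44):
            raise ValueError(f"{self.sample_id}: gestational week {self.gw} out of range")
        if self.group not in GROUPS and self.group not in (
            "mature_lt37",
            "mature_gt38",
        ):
            raise ValueError(f"{self.sample_id}: unknown group {self.group!r}")
        if self.flm_outcome not in OUTCOMES:
            raise ValueError(f"{self.sample_id}: unknown outcome {self.flm_outcome!r}")
        if self.lbc is not None and self.lbc < 0:
            raise ValueError(f"{self.sample_id}: LBC must be >= 0")

    def resolved_outcome(self) -> str:
        """Outcome used for evaluation; 18-GW controls resolve to premature."""
        if self.flm_outcome != "unknown":
            return self.flm_outcome
        if self.group == "control_18gw":
            return "premature"
        raise ValueError(f"{self.sample_id}: outcome unknown and not resolvable")


def _round_half_up_pct(numerator: int, denominator: int) -> int:
    if denominator == 0:
        return 0
    return int(math.floor(100.0 * numerator / denominator + 0.5))


@dataclass(frozen=True)
class ConfusionSummary:
    """Diagnostic confusion counts with premature as the positive class.

    Sensitivity and specificity are reported rounded half-up to whole
    percent, the convention of clinical method-comparison tables.
    """

    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity(self) -> int:
        return _round_half_up_pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> int:
        return _round_half_up_pct(self.tn, self.tn + self.fp)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def counts(self) -> tuple[int, int, int, int]:
        return (self.tp, self.fn, self.tn, self.fp)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "predicted_premature": {"premature": self.tp, "mature": self.fp},
                "predicted_mature": {"premature": self.fn, "mature": self.tn},
            }
        ).rename_axis("outcome")

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "sensitivity_pct": self.sensitivity,
            "specificity_pct": self.specificity,
        }


def ls_ratio(
    intensities: Sequence[float] | np.ndarray,
    species_names: Sequence[str],
    library: LipidLibrary,
    sample_id: str = "<sample>",
) -> float:
    """L/S ratio of one sample row.

    Sum of intensities over the lecithin panel divided by the sum over the
    sphingomyelin panel; invariant to any global scaling of the row, so it
    can be computed on raw or TIC-normalised intensities interchangeably.
    """
    values = pd.Series(np.asarray(intensities, dtype=float), index=list(species_names))
    lec = float(values.reindex(library.lecithin_names()).fillna(0.0).sum())
    sm = float(values.reindex(library.sphingomyelin_names()).fillna(0.0).sum())
    if sm <= 0:
        raise ValueError(f"{sample_id}: zero total sphingomyelin intensity, L/S undefined")
    return lec / sm


def ls_ratios(matrix: IntensityMatrix, library: LipidLibrary) -> pd.Series:
    """L/S ratio for every sample row of an intensity matrix."""
    return pd.Series(
        [
            ls_ratio(matrix.values[i], matrix.species_names, library, sid)
            for i, sid in enumerate(matrix.sample_ids)
        ],
        index=matrix.sample_ids,
        name="ls_ratio",
    )


def classify_ls(ratio: float, cutoff: float = DEFAULT_LS_CUTOFF) -> str:
    """Classify an L/S ratio: below the cutoff predicts premature lungs."""
    if ratio < 0:
        raise ValueError(f"L/S ratio must be >= 0, got {ratio}")
    return "premature" if ratio < cutoff else "mature"


def classify_lbc(count: float, cutoff: float = DEFAULT_LBC_CUTOFF) -> str:
    """Classify a lamellar body count (x10^9/L): below the cutoff predicts
    premature lungs."""
    if count < 0:
        raise ValueError(f"LBC must be >= 0, got {count}")
    return "premature" if count < cutoff else "mature"


def evaluate(
    records: Iterable[SampleRecord],
    classifier: str,
    cutoff: Optional[float] = None,
) -> ConfusionSummary:
    """Evaluate a classifier ('ls' or 'lbc') against resolved FLM outcomes."""
    if classifier not in ("ls", "lbc"):
        raise ValueError(f"unknown classifier {classifier!r} (use 'ls' or 'lbc')")
    if cutoff is None:
        cutoff = DEFAULT_LS_CUTOFF if classifier == "ls" else DEFAULT_LBC_CUTOFF

    records = list(records)
    missing = [
        r.sample_id
        for r in records
        if (r.ls_ratio is None if classifier == "ls" else r.lbc is None)
    ]
    if missing:
        raise ValueError(f"records missing {classifier} input: {missing}")

    tp = fn = tn = fp = 0
    for r in records:
        outcome = r.resolved_outcome()
        if classifier == "ls":
            pred = classify_ls(r.ls_ratio, cutoff)
        else:
            pred = classify_lbc(r.lbc, cutoff)
        if outcome == "premature":
            if pred == "premature":
                tp += 1
            else:
                fn += 1
        else:
            if pred == "mature":
                tn += 1
            else:
                fp += 1
    return ConfusionSummary(tp=tp, fn=fn, tn=tn, fp=fp)
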