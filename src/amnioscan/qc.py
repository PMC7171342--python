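"""Quality-control evaluation of replicate injections.

Pooled-sample QC injections interleaved with the study samples measure
platform precision: the per-species coefficient of variation (CV, %)
across replicates, averaged within lipid class, and the tightness of the
QC cluster in a PCA score plot.  Well-behaved targeted lipidomics runs
show class-average CVs of a few percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .extraction import IntensityMatrix
from .library import LipidLibrary

__all__ = ["QcReport", "qc_cv", "pca_scores", "plot_pca_scores"]


@dataclass
class QcReport:
    """Replicate-precision summary of a QC injection series."""

    per_species_cv: pd.Series          # % per species; NaN where mean is 0
    class_average_cv: dict[str, float]  # arithmetic mean of member-species CVs
    lecithin_average_cv: float
    sphingomyelin_average_cv: float
    n_replicates: int

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": f"class:{cls}", "average_cv_pct": cv}
            for cls, cv in sorted(self.class_average_cv.items())
        ]
        rows.append({"group": "lecithin", "average_cv_pct": self.lecithin_average_cv})
        rows.append(
            {"group": "sphingomyelin", "average_cv_pct": self.sphingomyelin_average_cv}
        )
        return pd.DataFrame(rows)


def _cv_percent(values: np.ndarray) -> float:
    mean = values.mean()
    if mean == 0:
        return float("nan")
    return float(values.std(ddof=1) / mean * 100.0)


def qc_cv(replicates: IntensityMatrix, library: LipidLibrary) -> QcReport:
    """Per-species and class-average CVs over QC replicate injections.

    CV uses the sample standard deviation (n-1 denominator).  Species with
    zero mean across replicates are reported as NaN and excluded from the
    class averages.
    """
    if replicates.shape[0] < 2:
        raise ValueError("at least 2 QC replicates are required for a CV")
    cvs = pd.Series(
        [_cv_percent(replicates.values[:, j]) for j in range(replicates.shape[1])],
        index=replicates.species_names,
        name="cv_pct",
    )
    by_name = {s.name: s for s in library}

    def _avg(names: list[str]) -> float:
        member = cvs.reindex([n for n in names if n in cvs.index]).dropna()
        return float(member.mean()) if len(member) else float("nan")

    classes = sorted({s.lipid_class for s in library})
    class_avg = {
        cls: _avg([s.name for s in library if s.lipid_class == cls]) for cls in classes
    }
    return QcReport(
        per_species_cv=cvs,
        class_average_cv=class_avg,
        lecithin_average_cv=_avg(library.lecithin_names()),
        sphingomyelin_average_cv=_avg(library.sphingomyelin_names()),
        n_replicates=replicates.shape[0],
    )


def pca_scores(
    matrix: IntensityMatrix,
    n_components: int = 2,
    scaling: str = "unit_variance",
) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and explained-variance fractions of the samples.

    ``scaling='center'`` mean-centers only; ``'unit_variance'`` (default,
    the chemometrics convention) additionally scales each species to unit
    variance, which requires every column to vary.
    """
    if scaling not in ("center", "unit_variance"):
        raise ValueError(f"unknown scaling {scaling!r}")
    n_samples, n_species = matrix.shape
    if n_components > min(n_samples - 1, n_species):
        raise ValueError(
            f"n_components={n_components} exceeds min(n_samples-1, n_species)="
            f"{min(n_samples - 1, n_species)}"
        )
    X = matrix.values.copy()
    X -= X.mean(axis=0)
    if scaling == "unit_variance":
        sd = X.std(axis=0, ddof=1)
        constant = [n for n, s in zip(matrix.species_names, sd) if s == 0]
        if constant:
            raise ValueError(
                f"unit-variance scaling impossible for constant species: {constant[:10]}"
            )
        X /= sd
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X)
    return scores, model.explained_variance_ratio_


def plot_pca_scores(scores: np.ndarray, labels, ax=None):
    """Scatter the first two PCA components, coloured by group label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    labels = np.asarray(labels)
    for group in pd.unique(labels):
        sel = labels == group
        ax.scatter(scores[sel, 0], scores[sel, 1], label=str(group), s=30)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend()
    return ax
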