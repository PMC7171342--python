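"""Biomarker discovery between mature and premature groups.

Species-level screening combines three filters, applied as strict
inequalities: a two-sided Welch t-test p-value below 0.05, a fold change
(ratio of mature to premature group means on TIC-normalised intensities)
above 2, and a variable-importance-for-projection (VIP) score above 1.1
from a partial-least-squares discriminant analysis (PLS-DA).

The PLS-DA is a univariate-response NIPALS fit: X is mean-centered and
unit-variance scaled, y is the 0/1 class indicator, centered.  Components
are extracted by iterative deflation; per-component explained y-variance
feeds the VIP score

    VIP_j = sqrt( p * sum_a SSY_a * w_aj^2 / sum_a SSY_a ),

with p the number of variables and w_a the unit-norm weight vector of
component a — so sum_j VIP_j^2 = p identically, and VIP > 1 marks a
variable of above-average influence on the projection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .extraction import IntensityMatrix

__all__ = [
    "BiomarkerRecord",
    "PLSDA",
    "PLSDAResults",
    "welch_t",
    "fold_change",
    "fit_plsda",
    "vip",
    "select_biomarkers",
    "biomarker_table",
    "DEFAULT_P_MAX",
    "DEFAULT_VIP_MIN",
    "DEFAULT_FC_MIN",
]

DEFAULT_P_MAX = 0.05
DEFAULT_VIP_MIN = 1.1
DEFAULT_FC_MIN = 2.0


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, p)`` with the Welch–Satterthwaite degrees of freedom.
    Two groups that are both constant and equal give ``t=0, p=1`` by
    convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a t-test")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("both groups constant with unequal means: t undefined")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fold_change(mean_mature: float, mean_premature: float) -> float:
    """Ratio of group means, mature over premature (unlogged)."""
    if not mean_premature > 0:
        raise ValueError(
            f"premature group mean must be positive for a fold change, got {mean_premature}"
        )
    return mean_mature / mean_premature


@dataclass
class PLSDAResults:
    """Fitted PLS-DA projection: weights, scores, loadings and VIPs."""

    model: "PLSDA"
    weights: np.ndarray           # (n_components, p), rows unit-norm
    scores: np.ndarray            # (n, n_components), mutually orthogonal
    loadings: np.ndarray          # (n_components, p)
    y_loadings: np.ndarray        # (n_components,)
    ssy: np.ndarray               # y sum-of-squares explained per component
    y_total_ss: float

    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def y_variance_explained(self) -> np.ndarray:
        """Fraction of centered-y variance explained per component."""
        if self.y_total_ss == 0:
            return np.zeros_like(self.ssy)
        return self.ssy / self.y_total_ss

    def vip(self) -> pd.Series:
        """Variable importance for the projection, one value per variable."""
        if not np.any(self.ssy > 0):
            raise ValueError("no predictive components: all explained y-variance is zero")
        p = self.weights.shape[1]
        w2 = self.weights**2  # rows already unit-norm
        vip2 = p * (self.ssy @ w2) / self.ssy.sum()
        return pd.Series(np.sqrt(vip2), index=self.model.feature_names, name="vip")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, self.n_components + 1),
                "y_variance_explained": self.y_variance_explained,
                "cumulative": np.cumsum(self.y_variance_explained),
            }
        )


class PLSDA:
    """Two-class partial least squares discriminant analysis (NIPALS).

    Parameters
    ----------
    X : array (n_samples, n_features)
        Predictor block, typically TIC-normalised intensities.
    y : array (n_samples,)
        Binary class labels (any two distinct values).
    n_components : int
        Number of latent components (default 2, the score-plot convention).
    scale : bool
        Autoscale X (mean-center + unit variance) before fitting; y is
        always centered.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: Sequence,
        n_components: int = 2,
        scale: bool = True,
        feature_names: Optional[Sequence[str]] = None,
    ) -> None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes = pd.unique(np.asarray(y))
        if len(classes) != 2:
            raise ValueError(f"PLS-DA needs exactly 2 classes, got {list(classes)}")
        self.classes_ = list(classes)
        self.y01 = np.asarray([self.classes_.index(v) for v in np.asarray(y)], float)
        if n_components < 1 or n_components > min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(f"n_components={n_components} out of range for X{X.shape}")
        self.n_components = n_components
        self.scale = scale
        self.feature_names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{j}" for j in range(X.shape[1])]
        )
        self.X = X

    @classmethod
    def from_matrix(
        cls,
        matrix: IntensityMatrix,
        labels: Sequence,
        n_components: int = 2,
        scale: bool = True,
    ) -> "PLSDA":
        m = matrix.drop_all_zero_species()
        return cls(
            m.values,
            labels,
            n_components=n_components,
            scale=scale,
            feature_names=m.species_names,
        )

    def fit(self) -> PLSDAResults:
        X = self.X - self.X.mean(axis=0)
        if self.scale:
            sd = X.std(axis=0, ddof=1)
            if (sd == 0).any():
                bad = [n for n, s in zip(self.feature_names, sd) if s == 0]
                raise ValueError(f"constant feature(s) under autoscaling: {bad[:10]}")
            X = X / sd
        y = self.y01 - self.y01.mean()
        y_total_ss = float(y @ y)

        A, (n, p) = self.n_components, X.shape
        W = np.zeros((A, p))
        T = np.zeros((n, A))
        P = np.zeros((A, p))
        C = np.zeros(A)
        ssy = np.zeros(A)
        Xa, ya = X.copy(), y.copy()
        for a in range(A):
            w = Xa.T @ ya
            norm = np.linalg.norm(w)
            if norm == 0:
                break  # residual y orthogonal to X: later components are null
            w /= norm
            t = Xa @ w
            tt = float(t @ t)
            if tt == 0:
                break
            pl = Xa.T @ t / tt
            c = float(ya @ t) / tt
            W[a], T[:, a], P[a], C[a] = w, t, pl, c
            ssy[a] = c * c * tt
            Xa = Xa - np.outer(t, pl)
            ya = ya - c * t
        return PLSDAResults(
            model=self,
            weights=W,
            scores=T,
            loadings=P,
            y_loadings=C,
            ssy=ssy,
            y_total_ss=y_total_ss,
        )


def fit_plsda(
    matrix: IntensityMatrix,
    labels: Sequence,
    n_components: int = 2,
    scale: bool = True,
) -> PLSDAResults:
    """Fit a PLS-DA on an intensity matrix (zero species dropped first)."""
    return PLSDA.from_matrix(matrix, labels, n_components=n_components, scale=scale).fit()


def vip(results: PLSDAResults) -> pd.Series:
    """VIP scores of a fitted PLS-DA (see :meth:`PLSDAResults.vip`)."""
    return results.vip()


@dataclass(frozen=True)
class BiomarkerRecord:
    """Per-species differential statistics and the selection verdict."""

    species_name: str
    fold_change: float
    vip: float
    p_value: float
    selected: bool = False


def select_biomarkers(
    records: Sequence[BiomarkerRecord],
    p_max: float = DEFAULT_P_MAX,
    vip_min: float = DEFAULT_VIP_MIN,
    fc_min: float = DEFAULT_FC_MIN,
) -> list[BiomarkerRecord]:
    """Apply the p < p_max, VIP > vip_min, FC > fc_min rule (all strict).

    Returns the selected records sorted by fold change descending, name
    ascending on ties; the result does not depend on input order.
    """
    if not (p_max > 0 and vip_min > 0 and fc_min > 0):
        raise ValueError("selection thresholds must be positive")
    chosen = [
        r
        for r in records
        if r.p_value < p_max and r.vip > vip_min and r.fold_change > fc_min
    ]
    chosen.sort(key=lambda r: (-r.fold_change, r.species_name))
    return [
        BiomarkerRecord(r.species_name, r.fold_change, r.vip, r.p_value, selected=True)
        for r in chosen
    ]


def biomarker_table(
    matrix: IntensityMatrix,
    labels: Sequence[str],
    positive: str = "mature",
    negative: str = "premature",
    n_components: int = 2,
    p_max: float = DEFAULT_P_MAX,
    vip_min: float = DEFAULT_VIP_MIN,
    fc_min: float = DEFAULT_FC_MIN,
) -> pd.DataFrame:
    """Full differential screen of mature vs premature samples.

    Computes, per species: mature/premature fold change of group means,
    Welch t-test p-value, PLS-DA VIP, and the selection verdict.  Expects
    a TIC-normalised matrix so that fold changes are composition ratios.
    No multiple-testing correction is applied; the rule filters on raw p.
    """
    labels = np.asarray(labels)
    mask_pos = labels == positive
    mask_neg = labels == negative
    if mask_pos.sum() < 2 or mask_neg.sum() < 2:
        raise ValueError(
            f"need >=2 samples per group; got {mask_pos.sum()} {positive!r} "
            f"and {mask_neg.sum()} {negative!r}"
        )
    m = matrix.drop_all_zero_species()
    sub = IntensityMatrix(
        sample_ids=[s for s, keep in zip(m.sample_ids, mask_pos | mask_neg) if keep],
        species_names=m.species_names,
        values=m.values[mask_pos | mask_neg],
        normalized=False,
    ).drop_all_zero_species()
    sub_labels = labels[mask_pos | mask_neg]
    res = fit_plsda(sub, sub_labels, n_components=n_components)
    vips = res.vip()

    pos_rows = sub.values[sub_labels == positive]
    neg_rows = sub.values[sub_labels == negative]
    rows = []
    for j, name in enumerate(sub.species_names):
        mean_pos, mean_neg = pos_rows[:, j].mean(), neg_rows[:, j].mean()
        fc = fold_change(mean_pos, mean_neg) if mean_neg > 0 else np.nan
        _, p = welch_t(pos_rows[:, j], neg_rows[:, j])
        rows.append(
            BiomarkerRecord(
                species_name=name,
                fold_change=fc,
                vip=float(vips[name]),
                p_value=p,
            )
        )
    selected_names = {
        r.species_name
        for r in select_biomarkers(
            [r for r in rows if np.isfinite(r.fold_change)],
            p_max=p_max,
            vip_min=vip_min,
            fc_min=fc_min,
        )
    }
    frame = pd.DataFrame(
        {
            "compound": [r.species_name for r in rows],
            "fold_change": [r.fold_change for r in rows],
            "vip": [r.vip for r in rows],
            "p_value": [r.p_value for r in rows],
            "selected": [r.species_name in selected_names for r in rows],
        }
    )
    return frame.sort_values(
        ["selected", "fold_change"], ascending=[False, False], kind="stable"
    ).reset_index(drop=True)
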