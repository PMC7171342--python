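"""Synthetic inputs with the statistical structure of late-pregnancy
amniotic-fluid lipidomics.

Raw clinical LC-HRMS data are rarely shareable, so every input the
pipeline consumes can be simulated here with the features that matter to
the downstream statistics:

* a 151-species targeted panel (88 PC, 27 PE, 23 SM, 13 Cer) of which
  exactly the 64 diacyl PCs are lecithins;
* log-normal lipid intensities with a configurable biological CV;
* a lecithin maturation surge — in samples with mature lungs the
  lecithin baseline is multiplied by a logistic function of gestational
  week (midpoint 36 GW, i.e. a rapid rise around 36 weeks), while
  sphingomyelin stays flat across gestation, so the L/S ratio climbs
  from ~1.7 at 18 GW into the tens at term;
* tight technical replicates for QC (class-average CVs near 3.8% for PC
  and 3.4% for SM);
* planted mature-vs-premature fold changes for biomarker-recovery
  studies;
* lamellar body counts that straddle the 50 x 10^9/L cutoff with a small
  overlap, mirroring how the count misclassifies a minority of samples.

A transcribed 33-sample clinical comparison cohort (L/S ratio, LBC,
gestational week, lung-maturity outcome) ships with the package as
``table1_fixture()``.

All generators take an explicit seed and are bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diagnostics import SampleRecord
from .extraction import PeakList
from .library import LipidLibrary, LipidSpecies, annotate_species, mz_for_adduct
from .pathway import PathwayDefinition

__all__ = [
    "CohortSpec",
    "LogisticRise",
    "generate_library",
    "generate_cohort",
    "generate_qc",
    "table1_fixture",
    "generate_toy_pathways",
    "TOY8_CENTRALITY",
    "PAPER_GROUP_SIZES",
]

#: Study-design group sizes: 6 mid-trimester controls, 8 premature,
#: 10 preterm-mature, 10 term-mature.
PAPER_GROUP_SIZES = {
    "control_18gw": 6,
    "premature": 8,
    "mature_lt37": 10,
    "mature_gt38": 10,
}

_ALL_GROUPS = tuple(PAPER_GROUP_SIZES)


# --------------------------------------------------------------------------
# Library generation
# --------------------------------------------------------------------------

_CHAINS = ["14:0", "15:0", "16:0", "16:1", "17:0", "18:0", "18:1", "18:2",
           "18:3", "19:0", "20:3", "20:4", "20:5", "22:4", "22:6"]

# Names fixed first so the catalogue contains the species the field's
# differential tables are usually built around.
_SEED_DIACYL_PC = ["PC(20:4/14:0)", "PC(20:4/20:3)", "PC(16:1/14:0)",
                   "PC(18:2/19:0)", "PC(16:0/18:1)", "PC(16:0/16:0)"]
_SEED_ETHER_O_PC = ["PC(O-16:0/18:1)"]
_SEED_ETHER_P_PC = ["PC(P-18:0/18:1)", "PC(P-18:0/20:4)"]
_SEED_LYSO_PC = ["PC(20:4/0:0)"]
_SEED_PE = ["PE(16:0/16:0)"]
_SEED_SM = ["SM(d16:1/17:0)"]


def _take_unique(seed_names: list[str], candidates, n: int) -> list[str]:
    names = list(seed_names)
    seen = set(names)
    for cand in candidates:
        if len(names) == n:
            break
        if cand not in seen:
            names.append(cand)
            seen.add(cand)
    if len(names) != n:
        raise RuntimeError(f"could not build {n} unique names")
    return names


def _library_names() -> list[str]:
    pairs = itertools.product(_CHAINS, _CHAINS)
    diacyl_pc = _take_unique(
        _SEED_DIACYL_PC, (f"PC({a}/{b})" for a, b in itertools.product(_CHAINS, _CHAINS)), 64
    )
    ether_o = _take_unique(
        _SEED_ETHER_O_PC, (f"PC(O-{a}/{b})" for a, b in pairs), 9
    )
    ether_p = _take_unique(
        _SEED_ETHER_P_PC,
        (f"PC(P-{a}/{b})" for a, b in itertools.product(_CHAINS, _CHAINS)),
        9,
    )
    lyso_pc = _take_unique(_SEED_LYSO_PC, (f"PC({a}/0:0)" for a in _CHAINS), 6)
    pe = _take_unique(
        _SEED_PE, (f"PE({a}/{b})" for a, b in itertools.product(_CHAINS, _CHAINS)), 27
    )
    sm = _take_unique(
        _SEED_SM, (f"SM(d18:1/{a})" for a in _CHAINS + ["24:1", "26:0", "26:1",
                                                        "21:0", "23:0", "25:0", "27:0", "13:0"]), 23
    )
    cer = _take_unique(
        [], (f"Cer(d18:1/{a})" for a in _CHAINS), 13
    )
    return diacyl_pc + ether_o + ether_p + lyso_pc + pe + sm + cer


def generate_library(seed: int) -> LipidLibrary:
    """A synthetic 151-species targeted panel.

    The class structure is fixed — 88 PC (64 diacyl = lecithin, 9 ether-O,
    9 ether-P, 6 lyso), 27 PE, 23 SM, 13 Cer — while neutral masses
    (uniform in [400, 900] Da, unique to 4 decimals) and expected
    retention times (uniform in [1, 13] min) are drawn from ``seed``.
    PE species are assigned the [M-H]- adduct, the rest [M+H]+.
    """
    rng = np.random.default_rng(seed)
    names = _library_names()
    masses: list[float] = []
    seen = set()
    while len(masses) < len(names):
        m = round(float(rng.uniform(400.0, 900.0)), 4)
        if m not in seen:
            seen.add(m)
            masses.append(m)
    rts = np.round(rng.uniform(1.0, 13.0, size=len(names)), 3)
    species = []
    for name, mass, rt in zip(names, masses, rts):
        cls, _, _, _ = annotate_species(name)
        adduct = "[M-H]-" if cls == "PE" else "[M+H]+"
        species.append(LipidSpecies.from_name(name, mass, adduct, float(rt)))
    return LipidLibrary(species=species)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticRise:
    """Logistic multiplier of the lecithin baseline as gestation advances.

    ``multiplier(gw) = 1 + (max_multiplier - 1) / (1 + exp(-steepness*(gw - midpoint)))``

    Defaults encode surfactant lecithin synthesis beginning around 28 GW
    with a rapid rise around 36 GW: midpoint 36 weeks, steepness
    0.8/week, 20-fold ceiling over the 18-GW baseline.
    """

    midpoint_gw: float = 36.0
    steepness: float = 0.8
    max_multiplier: float = 20.0

    def multiplier(self, gw: float) -> float:
        return 1.0 + (self.max_multiplier - 1.0) / (
            1.0 + np.exp(-self.steepness * (gw - self.midpoint_gw))
        )


@dataclass
class CohortSpec:
    """Design of a simulated amniotic-fluid cohort.

    ``seed`` is mandatory; there is no hidden global randomness.  When
    ``n_per_group`` is None each group uses the clinical study design
    sizes (6/8/10/10).  ``planted_biomarkers`` maps species names to true
    mature/premature fold changes applied on top of the maturation model.
    ``noise_cv`` is the per-species biological coefficient of variation
    (percent) of the log-normal intensity noise.
    """

    seed: int
    n_per_group: Optional[int] = None
    groups: tuple[str, ...] = _ALL_GROUPS
    lecithin_rise: LogisticRise = field(default_factory=LogisticRise)
    planted_biomarkers: dict[str, float] = field(default_factory=dict)
    noise_cv: float = 25.0
    baseline_ls: float = 1.7
    sample_scale_cv: float = 20.0
    n_decoy_peaks: int = 25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("CohortSpec.seed is mandatory")
        if self.n_per_group is not None and self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.noise_cv > 0:
            raise ValueError("noise_cv must be positive")
        unknown = set(self.groups) - set(_ALL_GROUPS)
        if unknown:
            raise ValueError(f"unknown groups: {sorted(unknown)}")

    def group_sizes(self) -> dict[str, int]:
        return {
            g: (self.n_per_group if self.n_per_group is not None else PAPER_GROUP_SIZES[g])
            for g in self.groups
        }


def _lognormal_sigma(cv_percent: float) -> float:
    """Log-normal shape parameter matching a target CV (multiplicative
    noise ``exp(N(0, sigma))`` has CV ``sqrt(exp(sigma^2) - 1)``)."""
    cv = cv_percent / 100.0
    return float(np.sqrt(np.log1p(cv * cv)))


_GROUP_OUTCOME = {
    "control_18gw": "unknown",
    "premature": "premature",
    "mature_lt37": "mature",
    "mature_gt38": "mature",
}

# LBC (x10^9/L) generating distributions: mid-trimester fluid is nearly
# acellular (~2); near-term counts centre in the fifties.  The premature
# spread is wide enough that ~10% of premature samples cross the 50
# cutoff, reproducing the count's known misclassification pattern.
_LBC_PARAMS = {
    "control_18gw": (2.0, 0.7),
    "premature": (40.0, 8.0),
    "mature_lt37": (57.0, 5.0),
    "mature_gt38": (57.0, 5.0),
}


def _draw_gw(rng: np.random.Generator, group: str) -> int:
    if group == "control_18gw":
        return 18
    if group == "premature":
        return int(rng.integers(30, 37))
    if group == "mature_lt37":
        return int(rng.integers(35, 37))
    return int(rng.integers(38, 41))


def generate_cohort(
    spec: CohortSpec, library: LipidLibrary
) -> tuple[list[PeakList], list[SampleRecord]]:
    """Simulate peak lists and metadata for a gestational-age cohort.

    Per species, intensities are log-normal around a per-species baseline
    (log-uniform across two decades).  Lecithin baselines are multiplied
    by the logistic gestational factor in samples with mature lungs —
    premature lungs have not initiated the surge — and sphingomyelin
    baselines are constant in gestational week.  Planted biomarkers are
    multiplied by their true fold change in mature samples.  Each peak
    carries a small mass error (uniform within ±3 ppm) and RT jitter
    (sd 0.03 min); decoy peaks at random m/z exercise matching
    specificity.
    """
    missing = [n for n in spec.planted_biomarkers if n not in library.names]
    if missing:
        raise ValueError(f"planted biomarkers absent from library: {missing}")

    rng = np.random.default_rng(spec.seed)
    n_species = len(library)
    baselines = 10.0 ** rng.uniform(5.0, 7.0, size=n_species)

    # Anchor the immature composition: scale lecithin baselines so the
    # baseline L/S ratio matches spec.baseline_ls (the mid-trimester value).
    is_lec = np.array([s.is_lecithin for s in library])
    is_sm = np.array([s.is_sphingomyelin for s in library])
    current = baselines[is_lec].sum() / baselines[is_sm].sum()
    baselines[is_lec] *= spec.baseline_ls / current

    sigma = _lognormal_sigma(spec.noise_cv)
    scale_sigma = _lognormal_sigma(spec.sample_scale_cv)
    planted_idx = {
        library.names.index(name): fc for name, fc in spec.planted_biomarkers.items()
    }
    target_mz = np.array([s.mz for s in library])
    target_rt = np.array([s.expected_rt for s in library])

    peaklists: list[PeakList] = []
    records: list[SampleRecord] = []
    counter = 0
    for group in spec.groups:
        for _ in range(spec.group_sizes()[group]):
            counter += 1
            sid = f"S{counter:03d}_{group}"
            gw = _draw_gw(rng, group)
            outcome = _GROUP_OUTCOME[group]
            is_mature = outcome == "mature"

            expected = baselines.copy()
            if is_mature:
                expected[is_lec] *= spec.lecithin_rise.multiplier(gw)
                for j, fc in planted_idx.items():
                    expected[j] *= fc
            sample_scale = float(np.exp(rng.normal(0.0, scale_sigma)))
            intensities = (
                expected * np.exp(rng.normal(0.0, sigma, size=n_species)) * sample_scale
            )

            mz = target_mz * (1.0 + rng.uniform(-3.0, 3.0, size=n_species) * 1e-6)
            rt = np.clip(target_rt + rng.normal(0.0, 0.03, size=n_species), 0.0, None)
            peaks = np.column_stack([mz, rt, intensities])
            if spec.n_decoy_peaks > 0:
                decoys = np.column_stack(
                    [
                        rng.uniform(100.0, 1500.0, size=spec.n_decoy_peaks),
                        rng.uniform(0.0, 15.0, size=spec.n_decoy_peaks),
                        10.0 ** rng.uniform(3.0, 4.0, size=spec.n_decoy_peaks),
                    ]
                )
                peaks = np.vstack([peaks, decoys])

            mean, sd = _LBC_PARAMS[group]
            lbc = float(max(0.0, rng.normal(mean, sd)))
            peaklists.append(PeakList(sample_id=sid, peaks=peaks))
            records.append(
                SampleRecord(
                    sample_id=sid, gw=gw, group=group, flm_outcome=outcome, lbc=lbc
                )
            )
    return peaklists, records


# --------------------------------------------------------------------------
# QC replicates
# --------------------------------------------------------------------------


def generate_qc(
    library: LipidLibrary,
    n_reps: int = 6,
    cv_target_pc: float = 3.8,
    cv_target_sm: float = 3.4,
    seed: int = 0,
) -> list[PeakList]:
    """Technical replicate injections of a pooled QC sample.

    Intensities are log-normal around a fixed pooled profile with a
    class-specific technical CV: ``cv_target_pc`` percent for PCs,
    ``cv_target_sm`` for SMs, and their mean for the remaining classes.
    Class-average CV estimates converge to the targets as ``n_reps``
    grows.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if not (cv_target_pc > 0 and cv_target_sm > 0):
        raise ValueError("CV targets must be positive")
    rng = np.random.default_rng(seed)
    n_species = len(library)
    baselines = 10.0 ** rng.uniform(5.0, 7.0, size=n_species)
    cv_other = 0.5 * (cv_target_pc + cv_target_sm)
    sigmas = np.array(
        [
            _lognormal_sigma(
                cv_target_pc
                if s.lipid_class == "PC"
                else cv_target_sm if s.lipid_class == "SM" else cv_other
            )
            for s in library
        ]
    )
    target_mz = np.array([s.mz for s in library])
    target_rt = np.array([s.expected_rt for s in library])
    replicates = []
    for i in range(n_reps):
        intensities = baselines * np.exp(rng.normal(0.0, sigmas, size=n_species))
        mz = target_mz * (1.0 + rng.uniform(-3.0, 3.0, size=n_species) * 1e-6)
        rt = np.clip(target_rt + rng.normal(0.0, 0.03, size=n_species), 0.0, None)
        replicates.append(
            PeakList(
                sample_id=f"QC{i + 1}",
                peaks=np.column_stack([mz, rt, intensities]),
            )
        )
    return replicates


# --------------------------------------------------------------------------
# Bundled clinical comparison cohort
# --------------------------------------------------------------------------


def table1_fixture() -> list[SampleRecord]:
    """The bundled 33-sample clinical comparison cohort.

    Each record carries the measured L/S ratio, the lamellar body count
    (x10^9/L), the sampling gestational week and the lung-maturity
    outcome (`control_18gw` marks the seven mid-trimester amniocentesis
    samples, which count as premature during evaluation).
    """
    path = resources.files("amnioscan.data").joinpath("table1_cohort.csv")
    with resources.as_file(path) as p:
        frame = pd.read_csv(p)
    records = []
    for row in frame.to_dict("records"):
        group = str(row["flm_outcome"])
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                gw=int(row["gw"]),
                group=group,
                flm_outcome="unknown" if group == "control_18gw" else group,
                lbc=float(row["lbc"]),
                ls_ratio=float(row["ls_ratio"]),
            )
        )
    return records


# --------------------------------------------------------------------------
# Toy pathway bundle
# --------------------------------------------------------------------------

#: Hand-derived relative betweenness for the 8-node toy tree below
#: (normalisation (n-1)(n-2)/2 = 21): removing t2 splits the tree into
#: branches of sizes 1/1/1/4 -> 15 cross pairs; t3 is symmetric.
TOY8_CENTRALITY = {
    "t1": 0.0,
    "t2": 15.0 / 21.0,
    "t3": 15.0 / 21.0,
    "t4": 0.0,
    "l1": 0.0,
    "l2": 0.0,
    "l3": 0.0,
    "l4": 0.0,
}


def generate_toy_pathways(seed: int = 0) -> list[PathwayDefinition]:
    """A deterministic toy pathway bundle for topology testing.

    Contains a 5-node star, a 3-node chain, a complete graph on 4 nodes
    (zero total centrality) and an 8-node tree whose centrality table is
    shipped as :data:`TOY8_CENTRALITY`.  The bundle is the same for every
    seed; the argument exists for interface uniformity.
    """
    star = PathwayDefinition(
        name="star",
        compounds=["center", "leaf1", "leaf2", "leaf3", "leaf4"],
        edges=[("center", f"leaf{i}") for i in (1, 2, 3, 4)],
    )
    chain = PathwayDefinition(
        name="chain", compounds=["a", "b", "c"], edges=[("a", "b"), ("b", "c")]
    )
    nodes = ["k1", "k2", "k3", "k4"]
    complete = PathwayDefinition(
        name="complete",
        compounds=nodes,
        edges=[(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]],
    )
    toy8 = PathwayDefinition(
        name="toy8",
        compounds=list(TOY8_CENTRALITY),
        edges=[
            ("t1", "t2"),
            ("t2", "t3"),
            ("t3", "t4"),
            ("t2", "l1"),
            ("t2", "l2"),
            ("t3", "l3"),
            ("t3", "l4"),
        ],
    )
    return [star, chain, complete, toy8]
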