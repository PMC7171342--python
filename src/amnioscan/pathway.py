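"""Metabolite-set enrichment and pathway topology impact.

Over-representation of the differential lipids in each pathway is scored
with a one-sided hypergeometric test against a background compound set,
with Holm step-down adjustment across the tested pathways.  Topological
importance of the hits within a pathway is summarised by the *impact*
score: the sum of relative betweenness centralities of the matched
compounds divided by the pathway's total centrality.  Impact runs from 0
(hits sit on the periphery) to 1 (hits carry all the shortest-path
traffic); a pathway whose graph has no intermediary nodes at all (e.g. a
complete graph) has zero total centrality and is assigned impact 0.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PathwayDefinition",
    "EnrichmentResult",
    "hypergeom_p",
    "holm_adjust",
    "relative_betweenness",
    "pathway_impact",
    "enrich",
    "load_pathways",
    "save_pathways",
]

logger = logging.getLogger(__name__)


@dataclass
class PathwayDefinition:
    """A named compound set with an undirected interaction graph."""

    name: str
    compounds: list[str]
    edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.compounds)) != len(self.compounds):
            raise ValueError(f"pathway {self.name}: duplicate compounds")
        members = set(self.compounds)
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"pathway {self.name}: self-loop on {a!r}")
            if a not in members or b not in members:
                raise ValueError(
                    f"pathway {self.name}: edge ({a!r}, {b!r}) references a non-member"
                )

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compounds)
        g.add_edges_from(self.edges)
        return g


@dataclass(frozen=True)
class EnrichmentResult:
    """Enrichment and topology scores for one pathway."""

    name: str
    raw_p: float
    holm_p: float
    neg_log_p: float
    impact: float
    hits: frozenset[str]
    pathway_size: int


def hypergeom_p(background_n: int, pathway_k: int, hits_n: int, overlap_k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap_k).

    Drawing ``hits_n`` compounds from a background of ``background_n`` of
    which ``pathway_k`` belong to the pathway, the p-value is the chance
    of seeing at least the observed overlap.
    """
    if min(background_n, pathway_k, hits_n, overlap_k) < 0:
        raise ValueError("counts must be non-negative")
    if pathway_k > background_n or hits_n > background_n:
        raise ValueError("pathway and hit sets cannot exceed the background")
    if overlap_k > min(pathway_k, hits_n):
        raise ValueError(
            f"overlap {overlap_k} exceeds min(pathway={pathway_k}, hits={hits_n})"
        )
    if overlap_k == 0:
        return 1.0
    return float(stats.hypergeom.sf(overlap_k - 1, background_n, pathway_k, hits_n))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjusted p-values, returned in input order."""
    p = list(map(float, p_values))
    if any(not (0.0 <= x <= 1.0) for x in p):
        raise ValueError("p-values must lie in [0, 1]")
    if not p:
        return []
    _, adjusted, _, _ = multipletests(p, method="holm")
    return [float(x) for x in adjusted]


def relative_betweenness(pathway: PathwayDefinition) -> dict[str, float]:
    """Betweenness centrality of each compound, normalised to [0, 1].

    Uses the undirected normalisation (n-1)(n-2)/2; unreachable pairs in
    disconnected graphs simply contribute nothing.
    """
    if not pathway.compounds:
        raise ValueError(f"pathway {pathway.name}: no compounds")
    return {
        node: float(c)
        for node, c in nx.betweenness_centrality(pathway.graph(), normalized=True).items()
    }


def pathway_impact(pathway: PathwayDefinition, matched: Iterable[str]) -> float:
    """Relative centrality mass of the matched compounds.

    Sum of relative betweenness over the matched compounds divided by the
    sum over all compounds; 0 when the pathway has no central nodes at
    all (zero denominator).
    """
    matched = set(matched)
    extra = matched - set(pathway.compounds)
    if extra:
        raise ValueError(
            f"pathway {pathway.name}: matched compounds not members: {sorted(extra)}"
        )
    centrality = relative_betweenness(pathway)
    total = sum(centrality.values())
    if total == 0:
        logger.info(
            "pathway %s has zero total centrality; impact reported as 0", pathway.name
        )
        return 0.0
    return sum(centrality[c] for c in matched) / total


def enrich(
    pathways: Sequence[PathwayDefinition],
    hits: Iterable[str],
    background: Iterable[str],
    log_base: str = "e",
) -> list[EnrichmentResult]:
    """Score every pathway against a hit list; sorted by raw p ascending.

    ``-log(p)`` uses the natural log by default (``log_base='10'`` for
    decadic).  Holm adjustment is applied across exactly the pathways
    tested in this call.
    """
    if log_base not in ("e", "10"):
        raise ValueError(f"log_base must be 'e' or '10', got {log_base!r}")
    background = set(background)
    if not background:
        raise ValueError("background compound set is empty")
    hits = set(hits)
    stray = hits - background
    if stray:
        raise ValueError(f"hits not in background: {sorted(stray)[:10]}")

    raw_ps, overlaps = [], []
    for pw in pathways:
        members = set(pw.compounds) & background
        overlap = hits & members
        raw_ps.append(hypergeom_p(len(background), len(members), len(hits), len(overlap)))
        overlaps.append(overlap)
    holm_ps = holm_adjust(raw_ps)

    log = math.log if log_base == "e" else math.log10
    results = []
    for pw, raw_p, holm_p, overlap in zip(pathways, raw_ps, holm_ps, overlaps):
        matched_members = overlap & set(pw.compounds)
        results.append(
            EnrichmentResult(
                name=pw.name,
                raw_p=raw_p,
                holm_p=holm_p,
                neg_log_p=-log(raw_p) if raw_p > 0 else math.inf,
                impact=pathway_impact(pw, matched_members),
                hits=frozenset(overlap),
                pathway_size=len(pw.compounds),
            )
        )
    results.sort(key=lambda r: (r.raw_p, r.name))
    return results


def results_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Tabulate enrichment results in the familiar -log(p) / impact layout."""
    return pd.DataFrame(
        {
            "pathway": [r.name for r in results],
            "raw_p": [r.raw_p for r in results],
            "holm_p": [r.holm_p for r in results],
            "neg_log_p": [r.neg_log_p for r in results],
            "impact": [r.impact for r in results],
            "n_hits": [len(r.hits) for r in results],
            "pathway_size": [r.pathway_size for r in results],
        }
    )


def load_pathways(path: str | Path) -> list[PathwayDefinition]:
    """Read pathways from JSON: one object or a list of
    ``{"name", "compounds": [...], "edges": [[a, b], ...]}``."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if isinstance(payload, Mapping):
        payload = [payload]
    return [
        PathwayDefinition(
            name=entry["name"],
            compounds=list(entry["compounds"]),
            edges=[tuple(e) for e in entry.get("edges", [])],
        )
        for entry in payload
    ]


def save_pathways(pathways: Sequence[PathwayDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            [
                {"name": p.name, "compounds": p.compounds, "edges": [list(e) for e in p.edges]}
                for p in pathways
            ],
            fh,
            indent=2,
        )
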