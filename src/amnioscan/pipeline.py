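"""End-to-end orchestration: peak lists (real or simulated) to report.

The pipeline sequences the library modules — extract, TIC-normalise, QC,
maturity diagnostics, differential screen, pathway enrichment — without
computing anything itself; every number in the report is produced by one
upstream operation.  Stages whose inputs are absent are skipped with a
logged reason.  A fixed config and seed give a byte-identical report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml

from . import __version__
from . import diagnostics as dx
from . import differential as diff
from . import extraction as ex
from . import io as aio
from . import pathway as pw
from . import qc as qcmod
from . import simulate as sim
from .library import LipidLibrary, default_library, load_library

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_DEFAULTS = {
    "ppm_tol": 5.0,
    "rt_window": 0.2,
    "ls_cutoff": 10.0,
    "lbc_cutoff": 50.0,
    "pls_components": 2,
    "p_max": 0.05,
    "vip_min": 1.1,
    "fc_min": 2.0,
    "log_base": "e",
}

_KNOWN_PATHS = {"library", "peaklists", "qc_peaklists", "cohort", "pathways", "out_dir"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    paths: dict[str, str] = field(default_factory=dict)
    simulate: Optional[dict[str, Any]] = None
    ppm_tol: float = _DEFAULTS["ppm_tol"]
    rt_window: float = _DEFAULTS["rt_window"]
    ls_cutoff: float = _DEFAULTS["ls_cutoff"]
    lbc_cutoff: float = _DEFAULTS["lbc_cutoff"]
    pls_components: int = _DEFAULTS["pls_components"]
    p_max: float = _DEFAULTS["p_max"]
    vip_min: float = _DEFAULTS["vip_min"]
    fc_min: float = _DEFAULTS["fc_min"]
    log_base: str = _DEFAULTS["log_base"]
    seed: int = 0

    def echo(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


def validate_config(source: str | Path | dict) -> RunConfig:
    """Parse and validate a YAML config file (or an equivalent dict).

    Missing parameters receive the documented defaults; unknown keys
    produce a warning, not an error; nonsensical thresholds and dangling
    paths are errors.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)

    known_sections = {"paths", "params", "simulate", "seed"}
    for key in set(raw) - known_sections:
        logger.warning("config: ignoring unknown key %r", key)

    paths = dict(raw.get("paths") or {})
    for key in set(paths) - _KNOWN_PATHS:
        logger.warning("config: ignoring unknown path key %r", key)
        paths.pop(key)
    for key, value in paths.items():
        if key == "out_dir":
            continue
        if not Path(value).exists():
            raise FileNotFoundError(f"config paths.{key}: no such file: {value}")

    params = dict(raw.get("params") or {})
    for key in set(params) - set(_DEFAULTS):
        logger.warning("config: ignoring unknown param %r", key)
        params.pop(key)
    merged = {**_DEFAULTS, **params}
    for key in ("ppm_tol", "rt_window", "ls_cutoff", "lbc_cutoff", "p_max", "vip_min", "fc_min"):
        if not float(merged[key]) > 0:
            raise ValueError(f"config params.{key} must be positive, got {merged[key]}")
    if int(merged["pls_components"]) < 1:
        raise ValueError("config params.pls_components must be >= 1")
    if merged["log_base"] not in ("e", "10"):
        raise ValueError("config params.log_base must be 'e' or '10'")

    return RunConfig(
        paths=paths,
        simulate=raw.get("simulate"),
        ppm_tol=float(merged["ppm_tol"]),
        rt_window=float(merged["rt_window"]),
        ls_cutoff=float(merged["ls_cutoff"]),
        lbc_cutoff=float(merged["lbc_cutoff"]),
        pls_components=int(merged["pls_components"]),
        p_max=float(merged["p_max"]),
        vip_min=float(merged["vip_min"]),
        fc_min=float(merged["fc_min"]),
        log_base=str(merged["log_base"]),
        seed=int(raw.get("seed", 0)),
    )


@dataclass
class RunReport:
    """Machine-readable result bundle of one run."""

    provenance: dict[str, Any]
    qc: dict[str, Any]
    diagnostics: dict[str, Any]
    biomarkers: dict[str, Any]
    pathways: dict[str, Any]

    def to_dict(self) -> dict[str, Any]:
        return {
            "provenance": self.provenance,
            "qc": self.qc,
            "diagnostics": self.diagnostics,
            "biomarkers": self.biomarkers,
            "pathways": self.pathways,
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**payload)


def _skipped(reason: str) -> dict[str, Any]:
    logger.info("stage skipped: %s", reason)
    return {"skipped": reason}


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage the config provides inputs for.

    Stage order: extract -> normalise -> QC -> diagnostics ->
    differential -> pathways.  Errors inside a stage propagate with the
    stage named in the message.
    """
    library = (
        load_library(config.paths["library"])
        if "library" in config.paths
        else default_library()
    )

    # ----- inputs: simulated or from files ---------------------------------
    peaklists = None
    qc_peaklists = None
    records = None
    if config.simulate is not None:
        simcfg = dict(config.simulate)
        spec = sim.CohortSpec(
            seed=int(simcfg.get("seed", config.seed)),
            n_per_group=simcfg.get("n_per_group"),
            noise_cv=float(simcfg.get("noise_cv", 25.0)),
            planted_biomarkers=dict(simcfg.get("planted_biomarkers", {})),
        )
        peaklists, records = sim.generate_cohort(spec, library)
        qc_peaklists = sim.generate_qc(library, seed=spec.seed)
    else:
        if "peaklists" in config.paths:
            peaklists = aio.read_peaklists_csv(config.paths["peaklists"])
        if "qc_peaklists" in config.paths:
            qc_peaklists = aio.read_peaklists_csv(config.paths["qc_peaklists"])
        if "cohort" in config.paths:
            records = aio.read_cohort_csv(config.paths["cohort"])

    # ----- extraction + normalisation --------------------------------------
    matrix = None
    if peaklists is not None:
        try:
            raw = ex.build_matrix(
                peaklists, library, ppm_tol=config.ppm_tol, rt_window=config.rt_window
            )
            matrix = ex.tic_normalize(raw)
        except Exception as exc:
            raise RuntimeError(f"stage extraction failed: {exc}") from exc

    # ----- QC ---------------------------------------------------------------
    if qc_peaklists is not None:
        try:
            qc_raw = ex.build_matrix(
                qc_peaklists, library, ppm_tol=config.ppm_tol, rt_window=config.rt_window
            )
            report = qcmod.qc_cv(ex.tic_normalize(qc_raw), library)
            nonzero = ex.tic_normalize(qc_raw).drop_all_zero_species()
            n_comp = min(2, len(qc_peaklists) - 1, nonzero.shape[1])
            _, evr = qcmod.pca_scores(nonzero, n_components=n_comp, scaling="center")
            qc_section = {
                "n_replicates": report.n_replicates,
                "class_average_cv_pct": {
                    k: round(v, 4) for k, v in report.class_average_cv.items()
                },
                "lecithin_average_cv_pct": round(report.lecithin_average_cv, 4),
                "sphingomyelin_average_cv_pct": round(report.sphingomyelin_average_cv, 4),
                "pca_explained_variance_fractions": [round(float(v), 6) for v in evr],
            }
        except Exception as exc:
            raise RuntimeError(f"stage qc failed: {exc}") from exc
    else:
        qc_section = _skipped("no QC peak lists provided")

    # ----- diagnostics ------------------------------------------------------
    if records is not None:
        try:
            if matrix is not None:
                ratios = dx.ls_ratios(matrix, library)
                for r in records:
                    if r.ls_ratio is None and r.sample_id in ratios.index:
                        r.ls_ratio = float(ratios[r.sample_id])
            diag: dict[str, Any] = {}
            if all(r.ls_ratio is not None for r in records):
                diag["ls"] = dx.evaluate(records, "ls", config.ls_cutoff).to_dict()
                diag["ls"]["cutoff"] = config.ls_cutoff
            if all(r.lbc is not None for r in records):
                diag["lbc"] = dx.evaluate(records, "lbc", config.lbc_cutoff).to_dict()
                diag["lbc"]["cutoff"] = config.lbc_cutoff
            diag_section = diag if diag else _skipped("no classifier inputs on records")
        except Exception as exc:
            raise RuntimeError(f"stage diagnostics failed: {exc}") from exc
    else:
        diag_section = _skipped("no cohort metadata provided")

    # ----- differential -----------------------------------------------------
    biomarker_frame = None
    if matrix is not None and records is not None:
        outcome_by_id = {
            r.sample_id: ("mature" if r.resolved_outcome() == "mature" else "premature")
            for r in records
        }
        unmatched = [s for s in matrix.sample_ids if s not in outcome_by_id]
        if unmatched:
            bio_section = _skipped(f"samples without metadata: {unmatched[:5]}")
            labels = np.array([])
        else:
            labels = np.array([outcome_by_id[s] for s in matrix.sample_ids])
        if labels.size and (labels == "mature").sum() >= 2 and (labels == "premature").sum() >= 2:
            try:
                biomarker_frame = diff.biomarker_table(
                    matrix,
                    labels,
                    n_components=config.pls_components,
                    p_max=config.p_max,
                    vip_min=config.vip_min,
                    fc_min=config.fc_min,
                )
                selected = biomarker_frame[biomarker_frame["selected"]]
                bio_section = {
                    "n_tested": int(len(biomarker_frame)),
                    "n_selected": int(len(selected)),
                    "selected": [
                        {
                            "compound": row["compound"],
                            "fold_change": round(float(row["fold_change"]), 4),
                            "vip": round(float(row["vip"]), 4),
                            "p_value": float(f"{row['p_value']:.6g}"),
                        }
                        for row in selected.to_dict("records")
                    ],
                }
            except Exception as exc:
                raise RuntimeError(f"stage differential failed: {exc}") from exc
        elif not unmatched:
            bio_section = _skipped("need >=2 samples in each outcome group")
    else:
        bio_section = _skipped("differential screen needs a matrix and metadata")

    # ----- pathways ---------------------------------------------------------
    if "pathways" in config.paths and biomarker_frame is not None:
        try:
            pathways = pw.load_pathways(config.paths["pathways"])
            background = set(biomarker_frame["compound"])
            for p in pathways:
                background |= set(p.compounds)
            hits = set(biomarker_frame.loc[biomarker_frame["selected"], "compound"])
            results = pw.enrich(pathways, hits, background, log_base=config.log_base)
            path_section = {
                "background_size": len(background),
                "n_hits": len(hits),
                "table": [
                    {
                        "pathway": r.name,
                        "raw_p": float(f"{r.raw_p:.6g}"),
                        "holm_p": float(f"{r.holm_p:.6g}"),
                        "neg_log_p": round(r.neg_log_p, 4),
                        "impact": round(r.impact, 4),
                        "n_hits": len(r.hits),
                    }
                    for r in results
                ],
            }
        except Exception as exc:
            raise RuntimeError(f"stage pathways failed: {exc}") from exc
    elif "pathways" in config.paths:
        path_section = _skipped("pathway stage needs a biomarker table")
    else:
        path_section = _skipped("no pathway definitions provided")

    provenance = {
        "tool": "amnioscan",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "library": {
            "n_species": len(library),
            "counts_by_class": library.counts_by_class,
            "n_lecithin": library.n_lecithin,
            "n_sphingomyelin": library.n_sphingomyelin,
        },
    }
    return RunReport(
        provenance=provenance,
        qc=qc_section,
        diagnostics=diag_section,
        biomarkers=bio_section,
        pathways=path_section,
    )
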