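"""End-to-end orchestration of the discovery and validation stages.

Wires the stages together from a single structured config (YAML or
dict): read or simulate run summaries -> link protein groups -> assemble
the log-ratio matrix -> pre-filter -> moderated tests -> impute ->
panel classifier -> confounder checks (discovery); then cross-platform
correlation -> corroboration -> incremental panels -> locked model
(validation).  Every artifact is written alongside a reproducibility
manifest naming the config hash, seed and package versions; all
randomness flows from the single root seed in the config.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classifier import (
    PanelClassifier,
    fit_lda,
    incremental_panels,
    score_samples,
)
from .confound import confounder_table
from .corroborate import corroborate_markers, cross_platform_correlation
from .design import SampleManifest, match_case_control
from .diffstats import moderated_t, prefilter
from .imputation import ImputeConfig, knn_impute
from .matrix import LINEAR_CONCENTRATION, QuantMatrix
from .pgca import (
    build_pgc_matrix,
    link_groups,
    qc_summary,
    read_protein_summaries,
    write_qc_report,
)
from .synthetic import SimConfig, read_run_layout, simulate_study


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""


def load_config(source: str | Path | Mapping[str, Any]) -> dict:
    if isinstance(source, Mapping):
        return dict(source)
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def config_hash(cfg: Mapping[str, Any]) -> str:
    return hashlib.sha1(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_manifest(outdir: Path, cfg: Mapping[str, Any], seed: int, extra: dict) -> None:
    payload = {
        "config_hash": config_hash(cfg),
        "seed": seed,
        "proteopanel_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        **extra,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(payload, fh, indent=2)


@dataclass
class DiscoveryBundle:
    """All discovery-stage artifacts, in memory."""

    matrix: QuantMatrix  # full PGC x sample log-ratio matrix
    prefiltered: QuantMatrix
    imputed: QuantMatrix
    results: pd.DataFrame  # moderated-t table over prefiltered rows
    candidates: list
    model: PanelClassifier | None
    scores: pd.DataFrame | None
    confounders: pd.DataFrame | None
    qc: dict
    labels: pd.Series
    manifest: SampleManifest
    pgc_of_protein: dict | None = None  # only for simulated inputs


def run_discovery(
    config: str | Path | Mapping[str, Any], outdir: str | Path | None = None
) -> DiscoveryBundle:
    """Execute the discovery stage; writes artifacts when ``outdir`` is set."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    params = dict(cfg.get("params", {}))
    alpha = float(params.get("alpha", 0.01))
    min_frac = float(params.get("min_frac", 2 / 3))
    knn_k = int(params.get("knn_k", 10))
    n_perm = int(params.get("n_perm", 999))

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    def fail(stage: str, exc: Exception) -> PipelineError:
        if out is not None:
            (out / "FAILED").write_text(f"{stage}: {exc}\n")
        return PipelineError(f"stage {stage!r} failed: {exc}")

    pgc_of_protein = None
    try:
        if "simulate" in cfg:
            sim_cfg = SimConfig(**{**cfg["simulate"], "seed": seed})
            study = simulate_study(sim_cfg)
            groups, manifest, layout = study.run_groups, study.manifest, study.run_layout
        else:
            inputs = cfg["inputs"]
            for key in ("summaries", "manifest", "layout"):
                if key not in inputs:
                    raise FileNotFoundError(f"config inputs missing {key!r}")
            paths = inputs["summaries"]
            paths = [paths] if isinstance(paths, (str, Path)) else list(paths)
            for p in [*paths, inputs["manifest"], inputs["layout"]]:
                if not Path(p).exists():
                    raise FileNotFoundError(f"input file not found: {p}")
            groups = read_protein_summaries(paths)
            manifest = SampleManifest.from_csv(inputs["manifest"])
            layout = read_run_layout(inputs["layout"])
            study = None
    except Exception as exc:
        raise fail("read", exc) from exc

    try:
        pgc_map = link_groups(groups)
        matrix = build_pgc_matrix(groups, pgc_map, layout, manifest=manifest)
        if study is not None:
            pgc_of_protein = study.protein_to_pgc(pgc_map)
        labels_all = manifest.labels()
        if params.get("match", False):
            cohort = match_case_control(manifest, ratio=int(params.get("match_ratio", 2)))
            keep = [s for s in cohort.sample_ids if s in matrix.values.columns]
        else:
            keep = [
                s for s in matrix.values.columns if labels_all.get(s) in ("AR", "NR")
            ]
        matrix_cc = matrix.restrict_cols(keep)
        labels = labels_all.loc[keep]
        qc = qc_summary(groups, pgc_map, labels=labels.to_dict(), run_layout=layout)
    except Exception as exc:
        raise fail("link", exc) from exc

    try:
        pre = prefilter(matrix_cc, labels, min_frac=min_frac)
        results, candidates = moderated_t(pre, labels, alpha=alpha)
        imputed, imputed_mask = knn_impute(pre, ImputeConfig(k=knn_k))
    except Exception as exc:
        raise fail("test", exc) from exc

    model = scores = conf_table = None
    try:
        if candidates:
            # panel ordered by discovery p-value
            panel = sorted(candidates, key=lambda r: results.loc[r, "p_value"])
            model = fit_lda(imputed, labels, panel=panel)
            scores = score_samples(model, imputed)
            conf_names = params.get("confounders", manifest.confounder_names)
            if conf_names:
                conf = manifest.confounders()[list(conf_names)].loc[labels.index]
                conf_table = confounder_table(
                    imputed.restrict_rows(panel),
                    labels,
                    conf,
                    scores=scores["score"],
                    n_perm=n_perm,
                    seed=seed,
                )
    except Exception as exc:
        raise fail("classify", exc) from exc

    bundle = DiscoveryBundle(
        matrix=matrix_cc,
        prefiltered=pre,
        imputed=imputed,
        results=results,
        candidates=candidates,
        model=model,
        scores=scores,
        confounders=conf_table,
        qc=qc,
        labels=labels,
        manifest=manifest,
        pgc_of_protein=pgc_of_protein,
    )

    if out is not None:
        pgc_map.to_tsv(out / "pgc_map.tsv")
        matrix_cc.to_tsv(out / "matrix.tsv")
        pre.to_tsv(out / "prefiltered.tsv")
        imputed.to_tsv(out / "imputed.tsv")
        results.to_csv(out / "results.tsv", sep="\t")
        (out / "candidates.txt").write_text("".join(f"{c}\n" for c in candidates))
        write_qc_report(qc, out / "qc.json")
        if model is not None:
            model.to_json(out / "model.json")
            scores.to_csv(out / "scores.tsv", sep="\t")
        if conf_table is not None:
            conf_table.to_csv(out / "confounders.tsv", sep="\t", index=False)
        _write_manifest(out, cfg, seed, {"stage": "discovery", "n_candidates": len(candidates)})
    return bundle


@dataclass
class ValidationBundle:
    correlation: pd.DataFrame
    corroboration: pd.DataFrame
    corroborated: list
    cv_reports: list
    locked_model: PanelClassifier | None
    status: str = "ok"  # "ok" or "no_panel"


def run_validation(
    discovery: DiscoveryBundle,
    platform_b: QuantMatrix,
    labels_b: pd.Series,
    id_map: Mapping | None = None,
    config: Mapping[str, Any] | None = None,
    outdir: str | Path | None = None,
) -> ValidationBundle:
    """Execute the validation stage against a second-platform table.

    Correlation on common samples, corroboration of discovery candidates
    at the relaxed alpha, incremental nested panels by discovery
    p-value order, and a final locked classifier on the corroborated
    panel.  An empty corroborated set yields an explicit ``no_panel``
    status rather than an error.
    """
    cfg = dict(config or {})
    seed = int(cfg.get("seed", 0))
    alpha = float(cfg.get("alpha", 0.05))
    k_folds = int(cfg.get("k_folds", 6))
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    candidates = discovery.candidates
    id_map = dict(id_map) if id_map is not None else {c: c for c in candidates}

    corr = cross_platform_correlation(discovery.matrix, platform_b, id_map=id_map)
    report = corroborate_markers(
        platform_b,
        labels_b,
        discovery.results,
        candidates=candidates,
        alpha=alpha,
        id_map=id_map,
    )

    cv_reports = []
    locked = None
    status = "ok"
    if report.corroborated:
        ordered = sorted(
            report.corroborated, key=lambda m: discovery.results.loc[m, "p_value"]
        )
        b_rows = [id_map[m] for m in ordered]
        b_log = platform_b.to_log2() if platform_b.scale == LINEAR_CONCENTRATION else platform_b
        common = [s for s in b_log.col_ids if s in labels_b.index
                  and labels_b[s] in ("AR", "NR")]
        b_cc = b_log.restrict_cols(common)
        y_b = labels_b.loc[common]
        cv_reports = incremental_panels(b_cc, y_b, b_rows, k=k_folds, seed=seed)
        locked = fit_lda(b_cc, y_b, panel=b_rows).lock()
    else:
        status = "no_panel"

    bundle = ValidationBundle(
        correlation=corr,
        corroboration=report.table,
        corroborated=report.corroborated,
        cv_reports=cv_reports,
        locked_model=locked,
        status=status,
    )
    if out is not None:
        corr.to_csv(out / "correlation.tsv", sep="\t", index=False)
        report.table.to_csv(out / "corroboration.tsv", sep="\t")
        with open(out / "cv_reports.json", "w") as fh:
            json.dump([r.to_dict() for r in cv_reports], fh, indent=2)
        if locked is not None:
            locked.to_json(out / "locked_model.json")
        else:
            (out / "NO_PANEL").write_text("no markers were corroborated\n")
        _write_manifest(out, cfg, seed, {"stage": "validation", "status": status})
    return bundle
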