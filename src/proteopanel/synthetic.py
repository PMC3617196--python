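"""Synthetic case-control proteomics studies with planted truth.

Emulates the structure of a reference-design isobaric-tag experiment:
each run labels three patient samples against a pooled reference channel,
so relative levels are comparable across runs.  Per-protein log ratios
are lognormal around a protein-specific baseline, with a class effect
added for a configurable set of planted markers whose default fold
changes (+1.28, -1.56, +1.46, +1.27, -1.31) match the magnitude of
rejection-regulated plasma proteins.  Detection is modelled at the
(run, protein) level — shotgun undersampling drops a protein from a
whole run, so missingness arrives in blocks of three samples.  A second
generator migrates the planted markers to a linear-concentration
platform with per-protein affine response and lognormal measurement
noise, optionally nulling chosen effects to exercise corroboration
failures.

Every random draw flows from the config seed; the emitted truth record
contains the full config, the planted effects, the per-sample latent
levels and the detection pattern, so tests can score any stage of the
pipeline against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import SampleManifest
from .matrix import LINEAR_CONCENTRATION, QuantMatrix
from .pgca import CHANNELS, PGCMap, RunGroup

LN2 = math.log(2.0)

#: default planted fold changes (protein row index -> signed linear fold change)
DEFAULT_PLANTED: tuple[tuple[int, float], ...] = (
    (5, +1.28),
    (150, -1.56),
    (188, +1.46),
    (84, +1.27),
    (92, -1.31),
)


@dataclass
class SimConfig:
    """Study conditions for the synthetic discovery experiment.

    ``cv_log`` is the standard deviation of natural-log ratios (the
    platform's log-scale coefficient of variation); ``detect_prob`` the
    per-(run, protein) detection probability, whose default is calibrated
    so roughly 14% of proteins survive the two-thirds detection
    pre-filter under the default 6 vs 14 design.
    """

    n_pgcs: int = 900
    n_case: int = 6
    n_control: int = 14
    cv_log: float = 0.25
    planted: tuple[tuple[int, float], ...] = DEFAULT_PLANTED
    detect_prob: float = 0.505
    runs_of_3: bool = True
    baseline_sd: float = 0.5
    extra_accession_prob: float = 0.5
    confounder_spec: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "weight_kg": (76.0, 25.0),
            "systolic_bp": (125.0, 18.0),
            "creatinine": (130.0, 55.0),
        }
    )
    confounder_leakage: str | None = None  # covariate name made class-dependent
    leakage_effect: float = 1.0  # class shift in SD units for the leaky covariate
    seed: int = 0

    def __post_init__(self) -> None:
        for idx, fc in self.planted:
            if not (0 <= idx < self.n_pgcs):
                raise ValueError(f"planted index {idx} out of range [0, {self.n_pgcs})")
            if abs(fc) <= 1:
                raise ValueError(f"planted |fold change| must exceed 1, got {fc}")
        if not (0 < self.detect_prob <= 1):
            raise ValueError("detect_prob must lie in (0, 1]")


def _accessions(g: int) -> tuple[str, list[str]]:
    anchor = f"ACC{g:04d}A"
    extras = [f"ACC{g:04d}B", f"ACC{g:04d}C"]
    return anchor, extras


@dataclass
class SimStudy:
    """One simulated discovery study: inputs plus the generating truth."""

    run_groups: list[RunGroup]
    manifest: SampleManifest
    run_layout: dict[str, dict[str, str]]
    truth: dict

    @property
    def labels(self) -> pd.Series:
        return self.manifest.labels()

    def anchor_of(self, protein: int) -> str:
        return _accessions(protein)[0]

    def protein_to_pgc(self, pgc_map: PGCMap) -> dict[int, int]:
        """Map generator protein indices to linked PGC codes via anchors."""
        by_acc: dict[str, int] = {}
        for pgc, members in pgc_map.members.items():
            for acc in members:
                by_acc[acc] = pgc
        return {
            g: by_acc[self.anchor_of(g)]
            for g in range(self.truth["config"]["n_pgcs"])
            if self.anchor_of(g) in by_acc
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit the file formats the readers consume (TSV/CSV/JSON)."""
        from .pgca import write_summaries

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "summaries": outdir / "protein_summaries.tsv",
            "manifest": outdir / "manifest.csv",
            "layout": outdir / "run_layout.csv",
            "truth": outdir / "truth.json",
        }
        write_summaries(self.run_groups, paths["summaries"])
        self.manifest.to_csv(paths["manifest"])
        with open(paths["layout"], "w") as fh:
            fh.write("run_id,channel,sample_id\n")
            for run_id, chans in self.run_layout.items():
                for channel, sample in chans.items():
                    fh.write(f"{run_id},{channel},{sample}\n")
        truth = dict(self.truth)
        truth["latent_log"] = {
            k: list(v) for k, v in self.truth["latent_log"].items()
        }
        with open(paths["truth"], "w") as fh:
            json.dump(truth, fh, indent=2, default=list)
        return paths


def read_run_layout(path: str | Path) -> dict[str, dict[str, str]]:
    df = pd.read_csv(path)
    layout: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        layout.setdefault(str(row["run_id"]), {})[str(row["channel"])] = str(row["sample_id"])
    return layout


def simulate_study(cfg: SimConfig | None = None) -> SimStudy:
    """Generate run summaries, manifest, run layout and truth record."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_case + cfg.n_control

    sample_ids = [f"S{i + 1:02d}" for i in range(n_samples)]
    classes = ["AR"] * cfg.n_case + ["NR"] * cfg.n_control
    weeks = rng.integers(1, 21, size=n_samples)
    ages = np.round(rng.normal(55, 10, size=n_samples), 1)
    sexes = rng.choice(["M", "F"], size=n_samples)

    conf_cols: dict[str, np.ndarray] = {}
    for name, (mean, sd) in cfg.confounder_spec.items():
        vals = rng.normal(mean, sd, size=n_samples)
        if cfg.confounder_leakage == name:
            vals = vals + cfg.leakage_effect * sd * (np.asarray(classes) == "AR")
        conf_cols[name] = np.round(vals, 2)

    manifest = SampleManifest(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "patient_id": [f"P{i + 1:02d}" for i in range(n_samples)],
                "class": classes,
                "week": weeks,
                "age": ages,
                "sex": sexes,
                **conf_cols,
            }
        )
    )

    # run layout: shuffle samples into runs of 3 patient channels + reference
    order = rng.permutation(n_samples)
    per_run = 3 if cfg.runs_of_3 else n_samples
    run_layout: dict[str, dict[str, str]] = {}
    for r, start in enumerate(range(0, n_samples, per_run)):
        chunk = order[start : start + per_run]
        run_layout[f"R{r + 1:02d}"] = {
            CHANNELS[i]: sample_ids[idx] for i, idx in enumerate(chunk)
        }

    # latent natural-log relative levels
    mu = rng.normal(0.0, cfg.baseline_sd, size=cfg.n_pgcs)
    delta = np.zeros(cfg.n_pgcs)
    for idx, fc in cfg.planted:
        delta[idx] = math.copysign(math.log(abs(fc)), fc)
    is_case = (np.asarray(classes) == "AR").astype(float)
    noise = rng.normal(0.0, cfg.cv_log, size=(cfg.n_pgcs, n_samples))
    latent = mu[:, None] + delta[:, None] * is_case[None, :] + noise

    # run-blocked detection
    run_ids = list(run_layout)
    detect = rng.random((len(run_ids), cfg.n_pgcs)) < cfg.detect_prob

    sample_col = {s: j for j, s in enumerate(sample_ids)}
    run_groups: list[RunGroup] = []
    detection_record: dict[str, list[int]] = {}
    for r, run_id in enumerate(run_ids):
        detected = np.where(detect[r])[0]
        detection_record[run_id] = detected.tolist()
        for local_id, g in enumerate(detected, start=1):
            anchor, extras = _accessions(int(g))
            accs = {anchor}
            for ex in extras:
                if rng.random() < cfg.extra_accession_prob:
                    accs.add(ex)
            ratios = {
                channel: float(math.exp(latent[g, sample_col[sample]]))
                for channel, sample in run_layout[run_id].items()
            }
            run_groups.append(
                RunGroup(
                    run_id=run_id,
                    local_group_id=local_id,
                    accessions=frozenset(accs),
                    top_accession=anchor,
                    unused_score=float(round(2.0 + rng.gamma(2.0, 2.0), 2)),
                    percent_coverage=float(round(rng.uniform(10, 80), 1)),
                    peptide_count=int(1 + rng.poisson(2.0)),
                    ratios=ratios,
                )
            )

    truth = {
        "config": dataclasses.asdict(cfg),
        "planted": [[int(i), float(fc)] for i, fc in cfg.planted],
        "mu": mu.tolist(),
        "delta_log": delta.tolist(),
        "detection": detection_record,
        "latent_log": {s: latent[:, j].tolist() for j, s in enumerate(sample_ids)},
        "anchor_accessions": {g: _accessions(g)[0] for g in range(cfg.n_pgcs)},
    }
    return SimStudy(run_groups=run_groups, manifest=manifest, run_layout=run_layout, truth=truth)


@dataclass
class PlatformB:
    """Second-platform concentration table with its own planted truth."""

    matrix: QuantMatrix  # linear concentrations, rows prot_<g>, cols samples
    labels: pd.Series
    bias: dict[int, tuple[float, float]]
    kept_effects: list[int]
    id_map_proteins: dict[int, str]  # generator protein index -> B row id


def simulate_platform_migration(
    study: SimStudy,
    keep_effects: Sequence[int] | None = None,
    noise_sd: float = 0.05,
    bias: Mapping[int, tuple[float, float]] | None = None,
    n_case: int = 30,
    n_control: int = 30,
    seed: int = 0,
    include_study_samples: bool = False,
) -> PlatformB:
    """Measure the planted proteins on a linear-concentration platform.

    Concentrations are a per-protein affine transform (intercept a,
    scale b) of the exponentiated latent log level, with multiplicative
    lognormal measurement noise of log-scale sd ``noise_sd``.  Effects
    are preserved only for ``keep_effects`` (default: all planted rows);
    proteins left out have their class effect nulled in the freshly drawn
    validation cohort, reproducing a corroboration failure.  With
    ``include_study_samples`` the original study samples are re-measured
    from their recorded latent levels, giving common samples for
    cross-platform correlation.
    """
    cfg_d = study.truth["config"]
    cv = cfg_d["cv_log"]
    planted = [int(i) for i, _ in study.truth["planted"]]
    if keep_effects is None:
        keep_effects = planted
    keep = set(int(k) for k in keep_effects)
    unknown = keep - set(planted)
    if unknown:
        raise ValueError(f"keep_effects not among planted rows: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    mu = np.asarray(study.truth["mu"])
    delta = np.asarray(study.truth["delta_log"])

    if bias is None:
        bias = {g: (0.0, float(np.exp(rng.normal(0.0, 0.3)))) for g in planted}
    else:
        bias = {int(g): (float(a), float(b)) for g, (a, b) in bias.items()}

    cols: dict[str, np.ndarray] = {}
    labels: dict[str, str] = {}

    if include_study_samples:
        latent_log = study.truth["latent_log"]
        study_labels = study.labels
        for s, vec in latent_log.items():
            arr = np.asarray(vec)
            cols[s] = arr[planted]
            labels[s] = str(study_labels[s])

    for i in range(n_case + n_control):
        cls = "AR" if i < n_case else "NR"
        sid = f"V{i + 1:03d}"
        eff = np.array([delta[g] if g in keep else 0.0 for g in planted])
        lat = mu[planted] + eff * (cls == "AR") + rng.normal(0.0, cv, size=len(planted))
        cols[sid] = lat
        labels[sid] = cls

    row_ids = [f"prot_{g}" for g in planted]
    data = {}
    for s, lat in cols.items():
        meas = []
        for j, g in enumerate(planted):
            a, b = bias[g]
            noise = math.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 1.0
            meas.append(a + b * math.exp(lat[j]) * noise)
        data[s] = meas
    matrix = QuantMatrix(
        pd.DataFrame(data, index=pd.Index(row_ids, name="protein")),
        scale=LINEAR_CONCENTRATION,
    )
    return PlatformB(
        matrix=matrix,
        labels=pd.Series(labels),
        bias=bias,
        kept_effects=sorted(keep),
        id_map_proteins={g: f"prot_{g}" for g in planted},
    )
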