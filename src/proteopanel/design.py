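"""Cohort construction and power for log-scale relative quantitation.

The discovery analysis is a case-control comparison at the event time:
one sample per patient (the first acute-rejection sample per case
patient), cases matched 1:2 to controls by time post-transplant and,
where possible, age and sex.  Power for the two-group comparison of
log-ratios is computed analytically from the noncentral t distribution,
with the measurement spread parameterised as the coefficient of
variation of log-scale ratios (sigma of the natural-log measurements).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from scipy import stats

CASE = "AR"
CONTROL = "NR"
MILD = "1R"
REQUIRED_COLUMNS = ("sample_id", "patient_id", "class", "week", "age", "sex")


@dataclass
class SampleManifest:
    """Per-sample clinical annotation.

    Wraps a DataFrame with columns sample_id, patient_id, class (AR / 1R /
    NR), week (weeks post-transplant), age, sex; any further columns are
    treated as confounder covariates (dose, weight, blood pressure, ...).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("sample_id values must be unique")
        bad = set(self.table["class"]) - {CASE, CONTROL, MILD}
        if bad:
            raise ValueError(f"unknown class labels: {sorted(bad)}")
        if (self.table["week"] < 0).any():
            raise ValueError("week must be non-negative")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def confounder_names(self) -> list[str]:
        return [c for c in self.table.columns if c not in REQUIRED_COLUMNS]

    def labels(self) -> pd.Series:
        """sample_id -> class label."""
        return self.table.set_index("sample_id")["class"]

    def confounders(self) -> pd.DataFrame:
        return self.table.set_index("sample_id")[self.confounder_names]


@dataclass
class Cohort:
    """Result of 1:ratio case-control matching."""

    case_samples: list[str]
    control_samples: list[str]
    table: pd.DataFrame  # one row per matched pair: case, control, deltas
    unmatched_controls: list[str] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return self.case_samples + self.control_samples


def match_case_control(
    manifest: SampleManifest,
    ratio: int = 2,
    keys: Sequence[str] = ("week", "age", "sex"),
) -> Cohort:
    """Greedy 1:ratio matching of AR cases to NR controls.

    One sample per patient: the earliest AR sample per case patient; for
    each control patient the NR sample nearest the case's week.  Cases are
    assigned up to ``ratio`` distinct control patients each, greedily by
    exact week first, then minimal |dweek|, ties broken by |dage| then sex
    match.  1R samples are excluded from both arms.  If there are fewer
    eligible controls than requested, a warning is issued and a partial
    matching returned.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    tab = manifest.table

    ar = tab[tab["class"] == CASE]
    if ar.empty:
        raise ValueError("no AR samples in manifest")
    # first AR sample per case patient
    cases = (
        ar.sort_values(["week", "sample_id"]).groupby("patient_id", sort=False).head(1)
    )
    cases = cases.sort_values(["week", "patient_id"])

    nr = tab[tab["class"] == CONTROL]
    control_patients = {
        pid: grp.sort_values(["week", "sample_id"]) for pid, grp in nr.groupby("patient_id")
    }

    rows = []
    used: set = set()
    for _, case in cases.iterrows():
        for _ in range(ratio):
            best = None
            for pid, grp in control_patients.items():
                if pid in used:
                    continue
                # earliest NR sample at the week nearest the case week
                dweeks = (grp["week"] - case["week"]).abs()
                idx = dweeks.idxmin()
                cand = grp.loc[idx]
                key = (
                    abs(cand["week"] - case["week"]),
                    abs(cand["age"] - case["age"]) if "age" in keys else 0.0,
                    0 if ("sex" in keys and cand["sex"] == case["sex"]) else 1,
                    str(pid),
                )
                if best is None or key < best[0]:
                    best = (key, pid, cand)
            if best is None:
                break
            _, pid, cand = best
            used.add(pid)
            rows.append(
                {
                    "case_sample": case["sample_id"],
                    "case_patient": case["patient_id"],
                    "control_sample": cand["sample_id"],
                    "control_patient": pid,
                    "case_week": case["week"],
                    "control_week": cand["week"],
                    "abs_dweek": abs(cand["week"] - case["week"]),
                    "abs_dage": abs(cand["age"] - case["age"]),
                    "sex_match": cand["sex"] == case["sex"],
                }
            )

    table = pd.DataFrame(rows)
    n_expected = ratio * len(cases)
    if len(table) < n_expected:
        warnings.warn(
            f"only {len(table)} controls matched for {len(cases)} cases "
            f"(requested {n_expected})",
            stacklevel=2,
        )
    unmatched = [
        grp.iloc[0]["sample_id"]
        for pid, grp in control_patients.items()
        if pid not in used
    ]
    return Cohort(
        case_samples=list(cases["sample_id"]),
        control_samples=list(table["control_sample"]) if len(table) else [],
        table=table,
        unmatched_controls=unmatched,
    )


@dataclass
class PowerSpec:
    """Two-group design on the log-ratio scale.

    ``fc`` is the fold change (ratio of mean relative levels), ``cv_log``
    the standard deviation of natural-log measurements, ``control_ratio``
    the number of controls per case.
    """

    fc: float
    cv_log: float = 0.25
    alpha: float = 0.01
    n_case: int = 6
    control_ratio: float = 2.0

    def __post_init__(self) -> None:
        if self.fc <= 0:
            raise ValueError("fold change must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.cv_log <= 0:
            raise ValueError("cv_log must be > 0")
        if self.n_case < 2:
            raise ValueError("n_case must be >= 2")
        if self.control_ratio <= 0:
            raise ValueError("control_ratio must be > 0")


def power_two_group(spec: PowerSpec) -> float:
    """Power of the two-sided two-sample t-test of log-ratios.

    Effect delta = |ln fc|, per-group sigma = cv_log, group sizes n_case
    and round(control_ratio * n_case); computed from the noncentral t
    distribution.  fc = 1 returns exactly alpha.
    """
    n1 = spec.n_case
    n2 = int(round(spec.control_ratio * spec.n_case))
    if n2 < 2:
        raise ValueError("control group size must be >= 2")
    delta = abs(math.log(spec.fc))
    df = n1 + n2 - 2
    ncp = delta / (spec.cv_log * math.sqrt(1 / n1 + 1 / n2))
    tcrit = stats.t.ppf(1 - spec.alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def required_n(
    fc: float,
    cv_log: float = 0.25,
    alpha: float = 0.01,
    target_power: float = 0.8,
    control_ratio: float = 2.0,
    n_max: int = 10**6,
) -> int:
    """Smallest n_case with power >= target_power (monotone bisection)."""
    probe = PowerSpec(fc, cv_log, alpha, 2, control_ratio)
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")

    def power_at(n: int) -> float:
        return power_two_group(PowerSpec(fc, cv_log, alpha, n, control_ratio))

    lo, hi = 2, 2
    while power_at(hi) < target_power:
        hi *= 2
        if hi > n_max:
            raise ValueError(f"target power {target_power} unreachable with n <= {n_max}")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid + 1
    return lo


def linear_cv_to_log_sd(cv_linear: float) -> float:
    """Convert a linear-scale CV to the log-scale standard deviation."""
    return math.sqrt(math.log1p(cv_linear**2))


def power_curve(
    fold_changes: Sequence[float],
    n_cases: Sequence[int],
    cv_log: float = 0.25,
    alpha: float = 0.01,
    control_ratio: float = 2.0,
) -> pd.DataFrame:
    """Power over a grid of fold changes and case-group sizes (CSV-friendly)."""
    rows = [
        {
            "fc": fc,
            "n_case": n,
            "n_control": int(round(control_ratio * n)),
            "power": power_two_group(PowerSpec(fc, cv_log, alpha, n, control_ratio)),
        }
        for fc in fold_changes
        for n in n_cases
    ]
    return pd.DataFrame(rows)
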