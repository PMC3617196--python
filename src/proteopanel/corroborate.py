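"""Cross-platform corroboration of discovery candidates.

Discovery candidates must survive migration to an independent platform
(targeted MS or immunoassay) before a panel is locked.  Two checks:

* technical corroboration — per-protein Spearman correlation between the
  platforms over common samples (rank-based, so monotone platform
  response curves do not matter); correlations <= 0.6 are flagged weak;
* statistical corroboration — the discovery test (moderated t) re-run on
  the new platform at a relaxed alpha (default 0.05); a marker is
  corroborated iff it is significant there AND its effect direction
  matches discovery.  Markers missing from the new platform are reported
  untestable rather than failed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import PriorEstimate, moderated_t
from .matrix import LINEAR_CONCENTRATION, QuantMatrix


def cross_platform_correlation(
    a: QuantMatrix,
    b: QuantMatrix,
    id_map: Mapping[str, str] | None = None,
    min_common: int = 4,
    weak_threshold: float = 0.6,
) -> pd.DataFrame:
    """Spearman correlation per protein between two platforms.

    ``id_map`` maps A's row ids to B's (identity if omitted).  Common
    samples are intersected by sample id; proteins with fewer than
    ``min_common`` common observations are reported with NaN r and a
    reason.  Returns an empty (but well-formed) table when the platforms
    share no samples.
    """
    if id_map is None:
        id_map = {r: r for r in a.row_ids if r in set(b.row_ids)}
    common_samples = [s for s in a.col_ids if s in set(b.col_ids)]
    rows = []
    for ida, idb in id_map.items():
        if ida not in a.values.index or idb not in b.values.index:
            rows.append({"protein": ida, "mapped_to": idb, "n_common": 0,
                         "r": np.nan, "weak": False, "note": "absent from a platform"})
            continue
        xa = a.values.loc[ida, common_samples]
        xb = b.values.loc[idb, common_samples]
        pair = pd.concat([xa, xb], axis=1).dropna()
        if len(pair) < min_common:
            rows.append({"protein": ida, "mapped_to": idb, "n_common": len(pair),
                         "r": np.nan, "weak": False, "note": "too few common samples"})
            continue
        r = float(stats.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic)
        rows.append({"protein": ida, "mapped_to": idb, "n_common": len(pair),
                     "r": r, "weak": bool(r <= weak_threshold), "note": ""})
    return pd.DataFrame(rows, columns=["protein", "mapped_to", "n_common", "r", "weak", "note"])


@dataclass
class CorroborationReport:
    """Outcome of re-testing discovery candidates on a second platform."""

    table: pd.DataFrame  # marker, p_value_b, direction_b, corroborated, untestable
    corroborated: list = field(default_factory=list)
    untestable: list = field(default_factory=list)


def corroborate_markers(
    b: QuantMatrix,
    labels: Mapping[str, str] | pd.Series,
    discovery_results: pd.DataFrame,
    candidates: Sequence | None = None,
    alpha: float = 0.05,
    id_map: Mapping | None = None,
    require_direction: bool = True,
    case: str = "AR",
    control: str = "NR",
) -> CorroborationReport:
    """Re-run the discovery test on platform B and check direction.

    ``discovery_results`` is the moderated-t table from the discovery
    platform (needs a ``fold_change`` column); ``candidates`` defaults to
    every row of it.  Linear-concentration platforms are log2-transformed
    first so effect directions are comparable with log-ratio discovery
    data.  The test is run over all rows of B (the variance prior is
    fitted on B's own rows; with fewer than 10 rows the ordinary t-test
    is used instead, with a warning).
    """
    if candidates is None:
        candidates = list(discovery_results.index)
    id_map = dict(id_map) if id_map is not None else {m: m for m in candidates}

    b_log = b.to_log2() if b.scale == LINEAR_CONCENTRATION else b
    if b_log.shape[0] >= 10:
        results_b, _ = moderated_t(b_log, labels, alpha=alpha, case=case, control=control)
    else:
        warnings.warn(
            "fewer than 10 rows on platform B: using the ordinary t-test (no shrinkage)",
            stacklevel=2,
        )
        results_b, _ = moderated_t(
            b_log, labels, prior=PriorEstimate.no_shrinkage(), alpha=alpha,
            case=case, control=control,
        )

    rows, corroborated, untestable = [], [], []
    for marker in candidates:
        mapped = id_map.get(marker)
        if mapped is None or mapped not in results_b.index:
            rows.append({"marker": marker, "p_value_b": np.nan, "fold_change_b": np.nan,
                         "direction_match": False, "corroborated": False, "untestable": True})
            untestable.append(marker)
            continue
        p_b = results_b.loc[mapped, "p_value"]
        fc_b = results_b.loc[mapped, "fold_change"]
        fc_a = discovery_results.loc[marker, "fold_change"]
        same_dir = bool(np.sign(fc_b) == np.sign(fc_a))
        ok = bool(p_b < alpha) and (same_dir or not require_direction)
        rows.append({"marker": marker, "p_value_b": float(p_b), "fold_change_b": float(fc_b),
                     "direction_match": same_dir, "corroborated": ok, "untestable": False})
        if ok:
            corroborated.append(marker)
    table = pd.DataFrame(rows).set_index("marker")
    return CorroborationReport(table=table, corroborated=corroborated, untestable=untestable)
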