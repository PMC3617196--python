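"""Validation stage: cross-platform corroboration and assay calibration.

The planted markers are re-measured on a linear-concentration platform
(targeted-assay style) with one effect deliberately nulled.  Spearman
correlation checks technical transfer on common samples; the moderated
test at alpha 0.05 with a matching effect direction decides
corroboration; the locked panel is then recalibrated on the new assay.
"""

import warnings

import pandas as pd

from proteopanel import (
    SimConfig,
    calibrate_panel,
    corroborate_markers,
    cross_platform_correlation,
    fit_lda,
    simulate_platform_migration,
    simulate_study,
)
from proteopanel.pgca import build_pgc_matrix, link_groups

study = simulate_study(SimConfig(seed=2))
planted = dict(study.truth["planted"])
weakest = min(planted, key=lambda g: abs(planted[g]))
print(f"planted effects: { {f'prot_{g}': fc for g, fc in planted.items()} }")
print(f"effect nulled on the new platform: prot_{weakest} ({planted[weakest]:+.2f})")

platform = simulate_platform_migration(
    study, keep_effects=[g for g in planted if g != weakest],
    n_case=30, n_control=30, seed=4, include_study_samples=True,
)

# technical corroboration on the re-measured study samples
pgc_map = link_groups(study.run_groups)
matrix = build_pgc_matrix(study.run_groups, pgc_map, study.run_layout)
p2p = study.protein_to_pgc(pgc_map)
id_map = {p2p[g]: f"prot_{g}" for g in planted if g in p2p}
corr = cross_platform_correlation(matrix, platform.matrix, id_map=id_map)
print("\nSpearman correlation between platforms (common samples):")
print(corr[["protein", "mapped_to", "n_common", "r", "weak"]].round(2).to_string(index=False))

# statistical corroboration on the fresh validation cohort
disc = pd.DataFrame(
    {"fold_change": [planted[g] for g in planted], "p_value": 0.005},
    index=[f"prot_{g}" for g in planted],
)
new_cohort = [s for s in platform.labels.index if s.startswith("V")]
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = corroborate_markers(
        platform.matrix.restrict_cols(new_cohort),
        platform.labels.loc[new_cohort], disc, alpha=0.05,
    )
print(f"\ncorroborated markers (p < 0.05, same direction): {report.corroborated}")

# lock the corroborated panel on the new platform, then recalibrate
b_log = platform.matrix.restrict_cols(new_cohort).to_log2()
locked = fit_lda(b_log, platform.labels.loc[new_cohort], panel=report.corroborated).lock()
rescaled = type(b_log)(b_log.values * 1.8 + 0.7, scale=b_log.scale)  # assay migration
recal, weight_report = calibrate_panel(locked, rescaled, platform.labels.loc[new_cohort])
print("\nweight comparison after migrating the assay:")
print(weight_report.round(3).to_string(index=False))
# Calibration keeps the panel fixed and refits only (weights, offset); with a
# per-protein affine response change the weight signs are preserved.
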