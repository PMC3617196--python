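"""Protein-group linking, summary parsing and matrix assembly."""

import math

import numpy as np
import pandas as pd
import pytest

from proteopanel.pgca import (
    LayoutError,
    PGCMap,
    RunGroup,
    SummaryParseError,
    build_pgc_matrix,
    link_groups,
    qc_summary,
    read_protein_summaries,
    write_summaries,
)


def make_group(run, n, accs, ratios=None, peptides=3, unused=4.0, cov=30.0):
    accs = frozenset(accs)
    return RunGroup(
        run_id=run,
        local_group_id=n,
        accessions=accs,
        top_accession=sorted(accs)[0],
        unused_score=unused,
        percent_coverage=cov,
        peptide_count=peptides,
        ratios=ratios or {},
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

SUMMARY = """run\tN\taccessions\ttop_accession\tunused\tpct_coverage\tpeptides\t115:114\t116:114\t117:114
R1\t1\tP1;P2\tP1\t4.2\t35.0\t3\t1.5\t\t0.8
R1\t2\tP3\tP3\t2.0\t20.0\t2\t2.0\t1.0\t1.0
R1\t3\tQ7;Q8;Q9\tQ7\t6.1\t55.5\t5\t\t\t
"""


def test_parse_three_row_fixture(tmp_path):
    f = tmp_path / "r1.tsv"
    f.write_text(SUMMARY)
    groups = read_protein_summaries([f])
    assert len(groups) == 3
    assert [g.accessions for g in groups] == [
        frozenset({"P1", "P2"}),
        frozenset({"P3"}),
        frozenset({"Q7", "Q8", "Q9"}),
    ]
    # absent ratio cells become absent entries, never zeros
    assert set(groups[0].ratios) == {"115:114", "117:114"}
    assert groups[2].ratios == {}


@pytest.mark.parametrize(
    "bad_row, match",
    [
        ("R1\t4\t\tP9\t1.0\t10\t1\t1.0\t\t", "empty accession"),
        ("R1\t4\tP9\tP9\t1.0\t10\t1\t-2.0\t\t", "strictly positive"),
        ("R1\t4\tP9\tP9\t1.0\t10\t1\t0\t\t", "strictly positive"),
    ],
)
def test_malformed_rows_name_file_and_line(tmp_path, bad_row, match):
    f = tmp_path / "bad.tsv"
    f.write_text(SUMMARY + bad_row + "\n")
    with pytest.raises(SummaryParseError, match="bad.tsv:5"):
        read_protein_summaries([f])


def test_roundtrip_write_read(tmp_path, small_study):
    f = tmp_path / "roundtrip.tsv"
    write_summaries(small_study.run_groups, f)
    back = read_protein_summaries([f])
    assert back == small_study.run_groups


def test_rungroup_invariants():
    with pytest.raises(ValueError):
        RunGroup("R1", 1, frozenset({"P1"}), "P2", 1.0, 10.0, 1, {})
    with pytest.raises(ValueError):
        make_group("R1", 1, ["P1"], ratios={"115:114": 0.0})


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

def test_transitive_sharing_merges():
    groups = [make_group("R1", 1, ["P1", "P2"]), make_group("R2", 1, ["P2", "P3"])]
    m = link_groups(groups)
    assert m.n_pgcs == 1
    assert m.members[1] == frozenset({"P1", "P2", "P3"})


def test_disjoint_groups_stay_apart():
    groups = [make_group("R1", 1, ["P1"]), make_group("R2", 1, ["P2"])]
    m = link_groups(groups)
    assert m.n_pgcs == 2
    assert m.members[1] & m.members[2] == frozenset()


def brute_force_closure(groups):
    """O(n^2) repeated transitive closure over accession sharing."""
    clusters = [{i} for i in range(len(groups))]
    changed = True
    while changed:
        changed = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                acc_i = set().union(*(groups[k].accessions for k in clusters[i]))
                acc_j = set().union(*(groups[k].accessions for k in clusters[j]))
                if acc_i & acc_j:
                    clusters[i] |= clusters[j]
                    del clusters[j]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(c) for c in clusters}


def random_instance(rng, n_groups=100, pool=300, n_runs=30):
    groups = []
    for i in range(n_groups):
        run = f"R{rng.integers(1, n_runs + 1)}"
        accs = rng.choice(pool, size=rng.integers(1, 4), replace=False)
        groups.append(make_group(run, i + 1, [f"A{a}" for a in accs]))
    return groups


def partition_of(m: PGCMap, groups):
    by_pgc = {}
    for i, g in enumerate(groups):
        by_pgc.setdefault(m.pgc_of(g), set()).add(i)
    return {frozenset(v) for v in by_pgc.values()}


@pytest.mark.parametrize("seed", range(10))
def test_linking_matches_bruteforce_closure(seed):
    rng = np.random.default_rng(seed)
    groups = random_instance(rng)
    assert partition_of(link_groups(groups), groups) == brute_force_closure(groups)


def test_idempotent_within_component():
    rng = np.random.default_rng(5)
    groups = random_instance(rng, n_groups=60)
    m = link_groups(groups)
    for pgc in list(m.members)[:5]:
        sub = [g for g in groups if m.pgc_of(g) == pgc]
        assert link_groups(sub).n_pgcs == 1


def test_order_invariant_up_to_relabeling():
    rng = np.random.default_rng(7)
    groups = random_instance(rng, n_groups=80)
    m1 = link_groups(groups)
    perm = list(rng.permutation(len(groups)))
    m2 = link_groups([groups[i] for i in perm])
    assert partition_of(m1, groups) == partition_of(m2, groups)
    # content-hash aliases are order-independent
    assert set(m1.aliases.values()) == set(m2.aliases.values())


def test_codes_assigned_in_first_appearance_order():
    groups = [
        make_group("R1", 1, ["X"]),
        make_group("R1", 2, ["Y"]),
        make_group("R2", 1, ["X", "Z"]),
    ]
    m = link_groups(groups)
    assert m.pgc_of(groups[0]) == 1
    assert m.pgc_of(groups[1]) == 2
    assert m.pgc_of(groups[2]) == 1


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

LAYOUT = {
    "R1": {"115:114": "s1", "116:114": "s2", "117:114": "s3"},
    "R2": {"115:114": "s4", "116:114": "s5", "117:114": "s6"},
}


def test_log2_transform_and_absence_propagation():
    groups = [
        make_group("R1", 1, ["P1"], ratios={"115:114": 2.0, "116:114": 1.0}),
        make_group("R2", 1, ["P9"], ratios={"115:114": 4.0}),
    ]
    m = link_groups(groups)
    qm = build_pgc_matrix(groups, m, LAYOUT)
    assert qm.values.loc[1, "s1"] == pytest.approx(1.0)
    assert qm.values.loc[1, "s2"] == pytest.approx(0.0)
    # PGC 1 absent from R2: all of R2's samples unobserved
    assert qm.observed.loc[1, ["s4", "s5", "s6"]].sum() == 0
    # ratio missing for channel 117 -> unobserved, not zero
    assert not qm.observed.loc[1, "s3"]


def test_hand_assembled_two_run_fixture():
    groups = [
        make_group("R1", 1, ["P1"], ratios={"115:114": 2.0}),
        make_group("R1", 2, ["P1b", "P1"], ratios={"115:114": 8.0}),  # same PGC, same run
        make_group("R2", 1, ["P1"], ratios={"115:114": 0.5}),
    ]
    m = link_groups(groups)
    qm = build_pgc_matrix(groups, m, LAYOUT)
    # two member groups in one run combined by median of log2 ratios
    assert qm.values.loc[1, "s1"] == pytest.approx(np.median([1.0, 3.0]))
    assert qm.values.loc[1, "s4"] == pytest.approx(-1.0)
    qm_mean = build_pgc_matrix(groups, m, LAYOUT, combine="mean")
    assert qm_mean.values.loc[1, "s1"] == pytest.approx(2.0)


def test_never_invents_values(small_study):
    m = link_groups(small_study.run_groups)
    qm = build_pgc_matrix(small_study.run_groups, m, small_study.run_layout)
    cooccur = len({(m.pgc_of(g), g.run_id) for g in small_study.run_groups})
    assert qm.observed.sum().sum() <= cooccur * 3


def test_duplicate_channel_assignment_rejected():
    layout = {"R1": {"115:114": "s1", "116:114": "s1"}}
    groups = [make_group("R1", 1, ["P1"], ratios={"115:114": 1.0})]
    with pytest.raises(LayoutError, match="two channels"):
        build_pgc_matrix(groups, link_groups(groups), layout)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------

def test_qc_peptide_fraction_boundaries():
    ones = [make_group(f"R{i}", 1, [f"P{i}"], peptides=1) for i in range(5)]
    rep = qc_summary(ones, link_groups(ones))
    assert rep["fraction_pgcs_with_2plus_peptides"] == 0.0

    mixed = [make_group(f"R{i}", 1, [f"P{i}"], peptides=3) for i in range(49)]
    mixed.append(make_group("R49", 1, ["PX"], peptides=1))
    rep = qc_summary(mixed, link_groups(mixed))
    assert rep["fraction_pgcs_with_2plus_peptides"] == pytest.approx(0.98)


def test_qc_medians_match_sort_oracle():
    rng = np.random.default_rng(3)
    groups = [
        make_group(f"R{r}", 1, ["SHARED"], unused=float(u), cov=float(c), peptides=int(p))
        for r, (u, c, p) in enumerate(
            zip(rng.uniform(0, 10, 9), rng.uniform(0, 100, 9), rng.integers(1, 8, 9))
        )
    ]
    rep = qc_summary(groups, link_groups(groups))
    rec = rep["per_pgc"][1]

    def median_by_sort(vals):
        s = sorted(vals)
        n = len(s)
        return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2

    assert rec["median_unused"] == pytest.approx(median_by_sort([g.unused_score for g in groups]))
    assert rec["median_coverage"] == pytest.approx(
        median_by_sort([g.percent_coverage for g in groups])
    )
    assert rec["mean_peptide_count"] == pytest.approx(
        np.mean([g.peptide_count for g in groups])
    )
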