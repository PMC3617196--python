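"""Protein-group linking across experimental runs (protein group codes).

Shotgun search engines report, per run, *protein groups*: minimal sets of
accessions that jointly explain the observed peptides.  Group composition
is unstable run-to-run, so comparing proteins across runs requires linking
groups that share evidence.  Two run-level groups are linked whenever they
share at least one accession; the connected components of the resulting
graph define global *protein group codes* (PGCs).  Any shared accession is
enough to merge — this accepts some chaining risk across isoform families,
which the QC report surfaces as the maximum component diameter.

PGC integers are assigned 1, 2, ... in order of first appearance in the
input, so a fixed file order gives reproducible codes; a content-hash alias
per PGC supports order-independent joins.
"""

from __future__ import annotations

import csv
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .matrix import LOG2_RATIO, QuantMatrix

CHANNELS = ("115:114", "116:114", "117:114")


class SummaryParseError(ValueError):
    """Malformed row in a protein summary file (names file and line)."""


class LayoutError(ValueError):
    """Inconsistent run layout (e.g. a sample on two channels)."""


@dataclass(frozen=True)
class RunGroup:
    """One protein group reported in one experimental run.

    ``ratios`` maps reporter-channel ratio names (e.g. ``"115:114"``) to
    strictly positive relative abundances; an absent channel means the
    group was not quantified for that sample, never zero.
    """

    run_id: str
    local_group_id: int
    accessions: frozenset[str]
    top_accession: str
    unused_score: float
    percent_coverage: float
    peptide_count: int
    ratios: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.accessions:
            raise ValueError(f"run {self.run_id} group {self.local_group_id}: empty accession set")
        if self.top_accession not in self.accessions:
            raise ValueError(
                f"run {self.run_id} group {self.local_group_id}: top accession "
                f"{self.top_accession!r} not among members"
            )
        if self.local_group_id <= 0:
            raise ValueError("local_group_id must be a positive integer")
        if self.unused_score < 0:
            raise ValueError("unused_score must be non-negative")
        if not (0 <= self.percent_coverage <= 100):
            raise ValueError("percent_coverage must lie in [0, 100]")
        if self.peptide_count < 0:
            raise ValueError("peptide_count must be non-negative")
        for ch, r in self.ratios.items():
            if not (r > 0):
                raise ValueError(
                    f"run {self.run_id} group {self.local_group_id}: "
                    f"ratio {ch} must be strictly positive, got {r}"
                )
        object.__setattr__(self, "ratios", dict(self.ratios))

    @property
    def key(self) -> tuple[str, int]:
        return (self.run_id, self.local_group_id)


@dataclass
class SummaryDialect:
    """Column mapping for tab-separated protein summary tables.

    The default mirrors the common search-engine export layout: run id,
    per-run group number N, semicolon-joined accessions, the chosen top
    accession, identification quality columns (Unused score, % coverage,
    unique peptide count) and one column per reporter ratio.
    """

    run_col: str = "run"
    group_col: str = "N"
    accessions_col: str = "accessions"
    top_col: str = "top_accession"
    unused_col: str = "unused"
    coverage_col: str = "pct_coverage"
    peptides_col: str = "peptides"
    ratio_cols: Mapping[str, str] = field(
        default_factory=lambda: {ch: ch for ch in CHANNELS}
    )
    accession_sep: str = ";"

    @property
    def columns(self) -> list[str]:
        return [
            self.run_col,
            self.group_col,
            self.accessions_col,
            self.top_col,
            self.unused_col,
            self.coverage_col,
            self.peptides_col,
            *self.ratio_cols.values(),
        ]


def read_protein_summaries(
    paths: Sequence[str | Path], dialect: SummaryDialect | None = None
) -> list[RunGroup]:
    """Parse tab-separated per-run protein group summaries into RunGroups.

    Absent ratio cells (empty fields) become absent entries.  Malformed
    rows raise :class:`SummaryParseError` naming the file and line.
    """
    dialect = dialect or SummaryDialect()
    groups: list[RunGroup] = []
    for path in paths:
        path = Path(path)
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                raise SummaryParseError(f"{path}: empty file")
            missing = [c for c in dialect.columns if c not in reader.fieldnames]
            if missing:
                raise SummaryParseError(f"{path}: missing columns {missing}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    accs = [
                        a.strip()
                        for a in row[dialect.accessions_col].split(dialect.accession_sep)
                        if a.strip()
                    ]
                    ratios: dict[str, float] = {}
                    for ch, col in dialect.ratio_cols.items():
                        cell = (row[col] or "").strip()
                        if cell:
                            ratios[ch] = float(cell)
                    grp = RunGroup(
                        run_id=row[dialect.run_col].strip(),
                        local_group_id=int(row[dialect.group_col]),
                        accessions=frozenset(accs),
                        top_accession=row[dialect.top_col].strip(),
                        unused_score=float(row[dialect.unused_col]),
                        percent_coverage=float(row[dialect.coverage_col]),
                        peptide_count=int(row[dialect.peptides_col]),
                        ratios=ratios,
                    )
                except (KeyError, ValueError) as exc:
                    raise SummaryParseError(f"{path}:{lineno}: {exc}") from exc
                groups.append(grp)
    return groups


def write_summaries(
    groups: Iterable[RunGroup], path: str | Path, dialect: SummaryDialect | None = None
) -> None:
    """Write RunGroups back to a single summary TSV (round-trips with the reader)."""
    dialect = dialect or SummaryDialect()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(dialect.columns)
        for g in groups:
            row = [
                g.run_id,
                str(g.local_group_id),
                dialect.accession_sep.join(sorted(g.accessions)),
                g.top_accession,
                repr(g.unused_score),
                repr(g.percent_coverage),
                str(g.peptide_count),
            ]
            for ch in dialect.ratio_cols:
                row.append(repr(g.ratios[ch]) if ch in g.ratios else "")
            writer.writerow(row)


@dataclass
class PGCMap:
    """Global partition of run-level groups into protein group codes.

    ``assignment`` maps (run_id, local_group_id) to the PGC integer;
    ``members`` maps each PGC to the union of member accessions.
    ``aliases`` gives a content hash of each PGC's accession set for
    order-independent joins between analyses.
    """

    assignment: dict[tuple[str, int], int]
    members: dict[int, frozenset[str]]
    aliases: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.aliases:
            self.aliases = {
                pgc: hashlib.sha1(",".join(sorted(accs)).encode()).hexdigest()[:12]
                for pgc, accs in self.members.items()
            }

    @property
    def n_pgcs(self) -> int:
        return len(self.members)

    def pgc_of(self, group: RunGroup) -> int:
        return self.assignment[group.key]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["pgc", "alias", "members"])
            for pgc in sorted(self.members):
                writer.writerow(
                    [pgc, self.aliases[pgc], ";".join(sorted(self.members[pgc]))]
                )


def link_groups(groups: Sequence[RunGroup]) -> PGCMap:
    """Link run-level protein groups into global protein group codes.

    Builds the graph whose nodes are run groups with an edge whenever two
    groups share >=1 accession; the connected components are the PGCs.
    Codes are assigned 1, 2, ... in order of first appearance of each
    component in the input ordering.
    """
    if not groups:
        raise ValueError("link_groups requires at least one run group")
    keys = [g.key for g in groups]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (run_id, local_group_id) among input groups")

    graph: nx.Graph = nx.Graph()
    graph.add_nodes_from(range(len(groups)))
    by_accession: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        for acc in g.accessions:
            by_accession.setdefault(acc, []).append(i)
    for nodes in by_accession.values():
        first = nodes[0]
        for other in nodes[1:]:
            graph.add_edge(first, other)

    component_of = {}
    for comp_id, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            component_of[node] = comp_id

    assignment: dict[tuple[str, int], int] = {}
    members: dict[int, set[str]] = {}
    code_of_component: dict[int, int] = {}
    next_code = 1
    for i, g in enumerate(groups):
        comp = component_of[i]
        if comp not in code_of_component:
            code_of_component[comp] = next_code
            next_code += 1
        pgc = code_of_component[comp]
        assignment[g.key] = pgc
        members.setdefault(pgc, set()).update(g.accessions)

    return PGCMap(assignment, {p: frozenset(a) for p, a in members.items()})


def build_pgc_matrix(
    groups: Sequence[RunGroup],
    pgc_map: PGCMap,
    run_layout: Mapping[str, Mapping[str, str]],
    combine: str = "median",
    manifest=None,
) -> QuantMatrix:
    """Assemble the PGC x sample matrix of log2 reporter ratios.

    ``run_layout`` maps run_id -> {channel -> sample_id} for the patient
    channels (115/116/117, each quantified against the pooled reference on
    114).  A PGC absent from a run leaves that run's samples unobserved.
    When several member groups of one PGC occur in the same run, their
    log2 ratios are combined by ``combine`` ("median", "mean" or "top" for
    the group whose top accession sorts first).  If a sample manifest is
    supplied, every sample in the layout must appear in it.
    """
    if combine not in ("median", "mean", "top"):
        raise ValueError(f"unknown combine rule {combine!r}")
    if manifest is not None:
        known = set(manifest.sample_ids)
        unknown = [
            s for chans in run_layout.values() for s in chans.values() if s not in known
        ]
        if unknown:
            raise LayoutError(f"samples in layout but not in manifest: {sorted(unknown)}")

    sample_channel: dict[str, tuple[str, str]] = {}
    for run_id, chans in run_layout.items():
        for channel, sample in chans.items():
            if channel not in CHANNELS:
                raise LayoutError(f"run {run_id}: unknown channel {channel!r}")
            if sample in sample_channel:
                raise LayoutError(f"sample {sample!r} assigned to two channels")
            sample_channel[sample] = (run_id, channel)

    samples = list(sample_channel)
    pgcs = sorted(pgc_map.members)
    # cell candidates: (pgc, sample) -> list of log2 ratios (one per member group)
    cells: dict[tuple[int, str], list[tuple[str, float]]] = {}
    for g in groups:
        if g.run_id not in run_layout:
            continue
        pgc = pgc_map.pgc_of(g)
        for channel, sample in run_layout[g.run_id].items():
            if channel in g.ratios:
                cells.setdefault((pgc, sample), []).append(
                    (g.top_accession, math.log2(g.ratios[channel]))
                )

    values = pd.DataFrame(np.nan, index=pd.Index(pgcs, name="pgc"), columns=samples)
    for (pgc, sample), entries in cells.items():
        vals = [v for _, v in entries]
        if combine == "median":
            values.loc[pgc, sample] = float(np.median(vals))
        elif combine == "mean":
            values.loc[pgc, sample] = float(np.mean(vals))
        else:  # top: deterministic representative by top accession order
            values.loc[pgc, sample] = sorted(entries)[0][1]
    return QuantMatrix(values, scale=LOG2_RATIO)


def qc_summary(
    groups: Sequence[RunGroup],
    pgc_map: PGCMap,
    labels: Mapping[str, str] | None = None,
    run_layout: Mapping[str, Mapping[str, str]] | None = None,
) -> dict:
    """Identification QC per PGC plus global quality fractions.

    Per PGC: median unused score, median percent coverage, mean unique
    peptide count across runs, and (when ``labels`` and ``run_layout`` are
    given) per-class counts of samples in which the PGC went undetected.
    Globally: the fraction of PGCs whose average peptide count is >= 2 and
    the maximum accession-sharing component diameter (chaining indicator).
    """
    per_pgc: dict[int, dict] = {}
    grouped: dict[int, list[RunGroup]] = {}
    for g in groups:
        grouped.setdefault(pgc_map.pgc_of(g), []).append(g)

    for pgc, members in grouped.items():
        rec = {
            "median_unused": float(np.median([g.unused_score for g in members])),
            "median_coverage": float(np.median([g.percent_coverage for g in members])),
            "mean_peptide_count": float(np.mean([g.peptide_count for g in members])),
            "n_runs": len({g.run_id for g in members}),
        }
        if labels is not None and run_layout is not None:
            runs_with = {g.run_id for g in members}
            missing_by_class: dict[str, int] = {}
            for run_id, chans in run_layout.items():
                for sample in chans.values():
                    if sample not in labels:
                        continue
                    if run_id not in runs_with:
                        cls = labels[sample]
                        missing_by_class[cls] = missing_by_class.get(cls, 0) + 1
            rec["missing_by_class"] = missing_by_class
        per_pgc[pgc] = rec

    counts = [rec["mean_peptide_count"] for rec in per_pgc.values()]
    frac_two_plus = float(np.mean([c >= 2 for c in counts])) if counts else float("nan")

    # chaining diagnostic: diameter of each PGC's accession-sharing graph
    max_diam = 0
    for pgc in grouped:
        sub = nx.Graph()
        members = grouped[pgc]
        sub.add_nodes_from(range(len(members)))
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[i].accessions & members[j].accessions:
                    sub.add_edge(i, j)
        if sub.number_of_nodes() > 1:
            max_diam = max(max_diam, nx.diameter(sub))

    return {
        "per_pgc": per_pgc,
        "fraction_pgcs_with_2plus_peptides": frac_two_plus,
        "max_component_diameter": max_diam,
        "n_pgcs": pgc_map.n_pgcs,
    }


def write_qc_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=str)
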