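"""Contig-to-gene collapsing and gene-diversity tables.

Assembled contigs that match the same reference gene are collapsed with the
half-length rule: contigs that differ in sequence but hit the same subject are
regions of a single gene when every one of them is shorter than half the
subject's length; otherwise each distinct contig counts as a separate gene.
Identical-sequence contigs (e.g. the same transcript assembled from two stage
libraries) are deduplicated before the rule is applied.

Mixed clusters — some members shorter than half the subject, some not — are
resolved by the rule's "otherwise" branch (each distinct contig is a gene) and
flagged in the audit output, because short members could alternatively be read
as regions of the long ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import CATEGORIES, AnnotatedContig
from .errors import ValidationError
from .io import DEFAULT_STAGES, StageLibrary

#: Label of the union-over-stages row in diversity tables.
ALL_STAGES = "all_stages"


@dataclass
class GeneCluster:
    """Contigs sharing one best-hit subject, collapsed to inferred genes."""

    subject_accession: str
    subject_length_bp: int
    members: list[AnnotatedContig]
    category: str
    family: str
    subfamily: str

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"cluster {self.subject_accession}: no members")
        for m in self.members:
            if m.best_hit is None or m.best_hit.subject_accession != self.subject_accession:
                raise ValidationError(
                    f"cluster {self.subject_accession}: member {m.contig.contig_id} "
                    "does not share the cluster subject"
                )

    def distinct_members(self) -> list[AnnotatedContig]:
        """Members after collapsing identical-sequence duplicates.

        Deduplication keys on the contig sequence when available (keeping the
        first occurrence in contig-id order); members without sequences are
        treated as distinct.
        """
        ordered = sorted(self.members, key=lambda m: m.contig.contig_id)
        seen: set[str] = set()
        distinct = []
        for m in ordered:
            seq = m.contig.sequence
            if seq is not None:
                if seq in seen:
                    continue
                seen.add(seq)
            distinct.append(m)
        return distinct

    @property
    def is_mixed(self) -> bool:
        """True when distinct members fall on both sides of the half-length cut."""
        half = self.subject_length_bp / 2
        lengths = [m.contig.length_bp for m in self.distinct_members()]
        return any(l < half for l in lengths) and any(l >= half for l in lengths)

    @property
    def inferred_gene_count(self) -> int:
        return count_genes(self)

    def contig_ids(self) -> list[str]:
        return [m.contig.contig_id for m in self.members]

    def stages_expressed(
        self, libraries: Sequence[StageLibrary] | None, stages: Sequence[str]
    ) -> set[str]:
        """Stages in which this gene cluster shows expression.

        A cluster is expressed in a stage when any member contig has >0 reads
        in that stage's library; without count data, the member contigs'
        library-of-origin labels are used instead.
        """
        if libraries is not None:
            expressed = set()
            for lib in libraries:
                if lib.stage not in stages:
                    raise ValidationError(f"unknown stage label {lib.stage!r}")
                if any(lib.reads(cid) > 0 for cid in self.contig_ids()):
                    expressed.add(lib.stage)
            return expressed
        labels = {m.contig.stage for m in self.members if m.contig.stage}
        unknown = labels - set(stages)
        if unknown:
            raise ValidationError(f"unknown stage label {sorted(unknown)[0]!r}")
        return labels


def count_genes(cluster: GeneCluster) -> int:
    """Number of genes inferred from one cluster under the half-length rule.

    After identical-sequence deduplication: if every member contig is shorter
    than half the subject gene's length, the contigs are different regions of
    a single gene (count 1); otherwise each distinct contig counts as a
    different gene.
    """
    if cluster.subject_length_bp is None or cluster.subject_length_bp <= 0:
        raise ValidationError(
            f"cluster {cluster.subject_accession}: subject length unknown; cannot apply rule"
        )
    distinct = cluster.distinct_members()
    half = cluster.subject_length_bp / 2
    if all(m.contig.length_bp < half for m in distinct):
        return 1
    return len(distinct)


def cluster_by_subject(annotated: Iterable[AnnotatedContig]) -> list[GeneCluster]:
    """Partition annotated contigs into one cluster per distinct best-hit subject.

    Input order is irrelevant: clusters come out sorted by subject accession
    and members sorted by contig id. Contigs without a significant best hit
    are not clusterable and raise.
    """
    groups: dict[str, list[AnnotatedContig]] = {}
    for a in annotated:
        if a.best_hit is None:
            raise ValidationError(
                f"contig {a.contig.contig_id} has no significant best hit; cannot cluster"
            )
        groups.setdefault(a.best_hit.subject_accession, []).append(a)
    clusters = []
    for accession in sorted(groups):
        members = sorted(groups[accession], key=lambda m: m.contig.contig_id)
        first = members[0]
        clusters.append(
            GeneCluster(
                subject_accession=accession,
                subject_length_bp=first.best_hit.subject_length_bp,
                members=members,
                category=first.category,
                family=first.family,
                subfamily=first.subfamily,
            )
        )
    return clusters


def detox_clusters(clusters: Iterable[GeneCluster]) -> list[GeneCluster]:
    """Clusters classified into one of the four detoxification categories."""
    return [c for c in clusters if c.category in CATEGORIES]


@dataclass
class DiversityTable:
    """Stage x category gene-diversity counts with totals.

    ``table`` rows are the stage order plus an :data:`ALL_STAGES` union row;
    columns are the four categories plus ``total``. Each row's total is the
    sum of its four category cells. The all-stages row counts every gene once
    over the union of stages, so it is generally less than the column sums.
    """

    table: pd.DataFrame

    def cell(self, stage: str, category: str) -> int:
        return int(self.table.loc[stage, category])

    def row_total(self, stage: str) -> int:
        return int(self.table.loc[stage, "total"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="stage")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiversityTable":
        df = pd.read_csv(path, sep="\t", index_col="stage")
        return cls(table=df)


def diversity_table(
    clusters: Sequence[GeneCluster],
    libraries: Sequence[StageLibrary] | None = None,
    stages: Sequence[str] = DEFAULT_STAGES,
) -> DiversityTable:
    """Per-stage, per-category inferred-gene counts (plus union row and totals).

    Cell (stage, category) sums ``inferred_gene_count`` over clusters of that
    category with read evidence in that stage. The all-stages row counts each
    cluster once if it is expressed anywhere.
    """
    detox = detox_clusters(clusters)
    index = list(stages) + [ALL_STAGES]
    table = pd.DataFrame(0, index=index, columns=list(CATEGORIES) + ["total"], dtype=int)
    for cluster in detox:
        expressed = cluster.stages_expressed(libraries, stages)
        n = cluster.inferred_gene_count
        for stage in expressed:
            table.loc[stage, cluster.category] += n
        if expressed:
            table.loc[ALL_STAGES, cluster.category] += n
    table["total"] = table[list(CATEGORIES)].sum(axis=1)
    return DiversityTable(table=table)


def _family_index(clusters: Sequence[GeneCluster]) -> list[tuple[str, str]]:
    """(family, subfamily) row order: family total row first, sub-rows after."""
    rows: list[tuple[str, str]] = []
    for c in clusters:
        fam = (c.family, "")
        if fam not in rows:
            rows.append(fam)
        if c.subfamily:
            sub = (c.family, c.subfamily)
            if sub not in rows:
                rows.append(sub)
    # group sub-rows under their family, preserving first-appearance order
    families = []
    for fam, sub in rows:
        if fam not in families:
            families.append(fam)
    ordered = []
    for fam in families:
        ordered.append((fam, ""))
        ordered.extend((f, s) for f, s in rows if f == fam and s)
    return ordered


def family_table(
    clusters: Sequence[GeneCluster],
    libraries: Sequence[StageLibrary] | None = None,
    stages: Sequence[str] = DEFAULT_STAGES,
) -> pd.DataFrame:
    """Family x stage gene counts with subfamily sub-rows.

    Rows are a (family, subfamily) MultiIndex; the subfamily-empty row is the
    family total, sub-rows (e.g. CYP4, CYP6, sigma-GST, epsilon-GST) count
    only clusters carrying that subfamily, so a sub-row never exceeds its
    family row. Columns are the stages plus an all-stages union column.
    """
    detox = detox_clusters(clusters)
    rows = _family_index(detox)
    cols = list(stages) + [ALL_STAGES]
    idx = pd.MultiIndex.from_tuples(rows or [("", "")], names=["family", "subfamily"])
    table = pd.DataFrame(0, index=idx, columns=cols, dtype=int)
    if not rows:
        return table.iloc[0:0]
    for cluster in detox:
        expressed = cluster.stages_expressed(libraries, stages)
        n = cluster.inferred_gene_count
        targets = [(cluster.family, "")]
        if cluster.subfamily:
            targets.append((cluster.family, cluster.subfamily))
        for target in targets:
            for stage in expressed:
                table.loc[target, stage] += n
            if expressed:
                table.loc[target, ALL_STAGES] += n
    return table


def species_comparison_table(
    clusters: Sequence[GeneCluster],
    species_counts: Mapping[str, pd.DataFrame | str | Path],
    focal_name: str = "this study",
) -> pd.DataFrame:
    """Family x species gene counts, merging externally supplied per-species tables.

    ``species_counts`` maps a species column name to a table (or TSV path)
    with columns ``family``, optional ``subfamily`` and ``count``-like third
    column. Families absent from a species are 0-filled.
    """
    detox = detox_clusters(clusters)
    rows = _family_index(detox)
    focal: dict[tuple[str, str], int] = {r: 0 for r in rows}
    for cluster in detox:
        n = cluster.inferred_gene_count
        focal[(cluster.family, "")] += n
        if cluster.subfamily:
            focal[(cluster.family, cluster.subfamily)] += n

    merged: dict[str, dict[tuple[str, str], int]] = {focal_name: focal}
    for species, source in species_counts.items():
        if not isinstance(source, pd.DataFrame):
            source = pd.read_csv(source, sep="\t", dtype={"family": str, "subfamily": str})
        df = source.fillna({"subfamily": ""}) if "subfamily" in source.columns else source.assign(subfamily="")
        count_col = [c for c in df.columns if c not in ("family", "subfamily")][0]
        col: dict[tuple[str, str], int] = {}
        for r in df.itertuples(index=False):
            key = (str(r.family), str(r.subfamily))
            col[key] = int(getattr(r, count_col))
            if key not in rows:
                rows.append(key)
        merged[species] = col

    idx = pd.MultiIndex.from_tuples(rows, names=["family", "subfamily"])
    out = pd.DataFrame(0, index=idx, columns=list(merged), dtype=int)
    for species, col in merged.items():
        for key, n in col.items():
            out.loc[key, species] = n
    return out


def cluster_audit(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    """Per-cluster audit trail: members, lengths, rule branch taken, mixed flag."""
    rows = []
    for c in clusters:
        distinct = c.distinct_members()
        half = c.subject_length_bp / 2
        if all(m.contig.length_bp < half for m in distinct):
            branch = "all_short"
        elif all(m.contig.length_bp >= half for m in distinct):
            branch = "all_long"
        else:
            branch = "mixed"
        rows.append(
            {
                "subject_accession": c.subject_accession,
                "subject_length_bp": c.subject_length_bp,
                "n_members": len(c.members),
                "n_distinct": len(distinct),
                "member_lengths_bp": ",".join(str(m.contig.length_bp) for m in distinct),
                "category": c.category,
                "family": c.family,
                "subfamily": c.subfamily,
                "rule_branch": branch,
                "mixed_flag": int(branch == "mixed"),
                "inferred_gene_count": c.inferred_gene_count,
            }
        )
    return pd.DataFrame(rows)
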