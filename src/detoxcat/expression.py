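"""Normalized expression statistics (RPKM) per gene and per gene group.

Two statistics, computed per stage library:

* per gene:  ``reads / (total mapped reads in millions x gene length in kb)``
* per group: ``total group reads / (total mapped reads in millions x mean
  gene length of the group in kb)``

1 RPKM = one read per kilobase of gene per million mapped reads. Values are
reported raw (not log-transformed). For a fragmented gene the effective
length is the sum of its distinct member-contig lengths, capped at the
reference subject's length so a fragmented gene never appears longer than
its reference.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import CATEGORIES
from .diversity import GeneCluster, detox_clusters
from .errors import ValidationError
from .io import DEFAULT_STAGES, StageLibrary


def gene_rpkm(reads: int, total_mapped_reads: int, gene_length_bp: int) -> float:
    """Reads per kilobase of gene per million mapped reads, for one gene."""
    if total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be > 0")
    if gene_length_bp <= 0:
        raise ValidationError("gene_length_bp must be > 0")
    if reads < 0:
        raise ValidationError("reads must be >= 0")
    return reads / ((total_mapped_reads / 1e6) * (gene_length_bp / 1000))


def group_rpkm(
    reads: Sequence[int], gene_lengths_bp: Sequence[int], total_mapped_reads: int
) -> float:
    """Cumulative RPKM for a group of genes.

    Total reads within the group, normalized by the library size in millions
    and the group's *average* gene length in kb. For equal-length genes this
    equals the sum of the members' individual RPKM values.
    """
    if len(reads) == 0 or len(gene_lengths_bp) == 0:
        raise ValidationError("group must be non-empty")
    if len(reads) != len(gene_lengths_bp):
        raise ValidationError("reads and gene_lengths_bp must have equal length")
    if total_mapped_reads <= 0:
        raise ValidationError("total_mapped_reads must be > 0")
    if any(l <= 0 for l in gene_lengths_bp):
        raise ValidationError("gene lengths must be > 0")
    if any(r < 0 for r in reads):
        raise ValidationError("reads must be >= 0")
    mean_length_kb = (sum(gene_lengths_bp) / len(gene_lengths_bp)) / 1000
    return sum(reads) / ((total_mapped_reads / 1e6) * mean_length_kb)


def cluster_length_bp(cluster: GeneCluster) -> int:
    """Effective gene length: distinct member lengths summed, capped at the subject."""
    total = sum(m.contig.length_bp for m in cluster.distinct_members())
    return min(total, cluster.subject_length_bp)


def cluster_reads(cluster: GeneCluster, library: StageLibrary) -> int:
    """Reads mapped to any member contig of the cluster in one stage library."""
    return sum(library.reads(cid) for cid in cluster.contig_ids())


def _group_key(cluster: GeneCluster, grouping: str) -> str:
    if grouping == "family":
        return cluster.family
    if grouping == "category":
        return cluster.category
    if grouping == "gene":
        return cluster.subject_accession
    raise ValidationError(f"unknown grouping {grouping!r} (expected family, category or gene)")


def expression_profiles(
    clusters: Sequence[GeneCluster],
    libraries: Sequence[StageLibrary],
    grouping: str = "family",
    stages: Sequence[str] = DEFAULT_STAGES,
) -> pd.DataFrame:
    """Long-format RPKM table: one row per (group, stage).

    Groups are enzyme families, categories, or individual genes (clusters).
    Genes with no reads in a stage contribute 0; rows are sorted by group
    then by the given stage order. Library input order does not matter.
    """
    if grouping not in ("family", "category", "gene"):
        raise ValidationError(f"unknown grouping {grouping!r} (expected family, category or gene)")
    detox = detox_clusters(clusters)
    by_stage = {lib.stage: lib for lib in libraries}
    unknown = set(by_stage) - set(stages)
    if unknown:
        raise ValidationError(f"unknown stage label {sorted(unknown)[0]!r}")

    groups: dict[str, list[GeneCluster]] = {}
    for c in detox:
        groups.setdefault(_group_key(c, grouping), []).append(c)

    if grouping == "category":
        order = [c for c in CATEGORIES if c in groups]
    else:
        order = sorted(groups)

    rows = []
    for group in order:
        members = groups[group]
        lengths = [cluster_length_bp(c) for c in members]
        for stage in stages:
            lib = by_stage.get(stage)
            if lib is None:
                continue
            reads = [cluster_reads(c, lib) for c in members]
            rows.append(
                {
                    "group": group,
                    "stage": stage,
                    "reads": sum(reads),
                    "length_kb": sum(lengths) / len(lengths) / 1000,
                    "rpkm": group_rpkm(reads, lengths, lib.total_mapped_reads),
                }
            )
    return pd.DataFrame(rows, columns=["group", "stage", "reads", "length_kb", "rpkm"])


def plot_profiles(
    profiles: pd.DataFrame,
    outdir: str | Path,
    stages: Sequence[str] = DEFAULT_STAGES,
    fmt: str = "png",
) -> list[Path]:
    """Optional plotting hook: one bar profile per group across stages."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for group, sub in profiles.groupby("group", sort=True):
        sub = sub.set_index("stage").reindex([s for s in stages if s in set(sub["stage"])])
        fig, ax = plt.subplots(figsize=(6, 3))
        ax.bar(sub.index, sub["rpkm"], color="#4878a8")
        ax.set_ylabel("RPKM")
        ax.set_title(str(group))
        ax.tick_params(axis="x", rotation=45)
        fig.tight_layout()
        safe = "".join(ch if ch.isalnum() or ch in "-_" else "_" for ch in str(group))
        path = outdir / f"profile_{safe}.{fmt}"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
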