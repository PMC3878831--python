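"""End-to-end pipeline composition, run summaries and consistency checks."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotation import (
    CATEGORIES,
    DEFAULT_EVALUE_THRESHOLD,
    FamilyOntology,
    annotate,
    evalue_diagnostic,
    flag_contaminants,
)
from .diversity import (
    ALL_STAGES,
    DiversityTable,
    cluster_audit,
    cluster_by_subject,
    diversity_table,
    family_table,
)
from .errors import ConfigError, DetoxcatError, ValidationError
from .expression import expression_profiles
from .io import (
    DEFAULT_STAGES,
    read_counts,
    read_fasta,
    read_hits,
    read_taxonomy_map,
    write_annotation,
)

log = logging.getLogger("detoxcat")


def summarize_reads(read_count: int, total_bases: int) -> int:
    """Mean read length in bp, rounded half-up to the nearest integer."""
    if read_count <= 0:
        raise ValidationError("read_count must be > 0")
    if total_bases < 0:
        raise ValidationError("total_bases must be >= 0")
    return int(math.floor(total_bases / read_count + 0.5))


def check_table_consistency(table: DiversityTable | pd.DataFrame) -> list[str]:
    """Verify each stage row's total equals the sum of its four category cells.

    Returns one named violation per inconsistent row; an empty list means the
    table is internally consistent. Works on pipeline output and on
    externally transcribed published tables alike.
    """
    df = table.table if isinstance(table, DiversityTable) else table
    violations = []
    if df.empty:
        return violations
    missing = [c for c in (*CATEGORIES, "total") if c not in df.columns]
    if missing:
        raise ValidationError(f"diversity table missing column {missing[0]!r}")
    for stage, row in df.iterrows():
        cell_sum = int(sum(row[c] for c in CATEGORIES))
        if cell_sum != int(row["total"]):
            violations.append(
                f"{stage}: category cells sum to {cell_sum} but total column says {int(row['total'])}"
            )
    return violations


def reference_diversity_table() -> DiversityTable:
    """The published B. huntii stage x category gene-diversity counts."""
    ref = resources.files("detoxcat.data").joinpath("bhuntii_stage_diversity.tsv")
    with resources.as_file(ref) as path:
        return DiversityTable.from_tsv(path)


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run."""

    contigs: Path
    hits: Path
    counts: Path | None = None
    ontology: Path | None = None
    taxonomy_map: Path | None = None
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD
    stages: Sequence[str] = DEFAULT_STAGES
    outdir: Path = Path("detoxcat_out")
    seed: int = 0
    verbosity: int = 0

    def __post_init__(self) -> None:
        if self.evalue_threshold <= 0:
            raise ConfigError("evalue_threshold must be > 0")
        for name in ("contigs", "hits", "counts", "ontology", "taxonomy_map"):
            value = getattr(self, name)
            if value is None:
                continue
            path = Path(value)
            setattr(self, name, path)
            if not path.exists():
                raise ConfigError(f"{name} file not found: {path}")
        self.outdir = Path(self.outdir)


@dataclass
class RunSummary:
    """Machine-readable summary of one pipeline run."""

    n_contigs: int
    n_hits: int
    n_significant_contigs: int
    fraction_e_le_1e5: float
    removed_fractions: dict[str, float]
    n_removed: int
    n_detox_genes: int
    detox_genes_by_category: dict[str, int]
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_contigs": self.n_contigs,
            "n_hits": self.n_hits,
            "n_significant_contigs": self.n_significant_contigs,
            "fraction_e_le_1e5": self.fraction_e_le_1e5,
            "removed_fractions": self.removed_fractions,
            "n_removed": self.n_removed,
            "n_detox_genes": self.n_detox_genes,
            "detox_genes_by_category": self.detox_genes_by_category,
            "outputs": self.outputs,
        }


def run_pipeline(config: RunConfig) -> RunSummary:
    """Annotate, de-contaminate, collapse, count and normalize in one pass.

    Writes annotation, contamination-summary, diversity, family, expression
    and audit tables under ``config.outdir``. Any stage failure removes the
    partial outputs and re-raises with the stage named.
    """
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write(name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        written.append(path)
        return path

    stage_name = "load"
    try:
        contigs = read_fasta(config.contigs)
        hits = read_hits(
            config.hits,
            taxonomy_map=read_taxonomy_map(config.taxonomy_map) if config.taxonomy_map else None,
        )
        libraries = read_counts(config.counts) if config.counts else None
        ontology = (
            FamilyOntology.from_file(config.ontology)
            if config.ontology
            else FamilyOntology.default()
        )

        stage_name = "annotation"
        annotated = annotate(contigs, hits, ontology, config.evalue_threshold)
        clean, contamination = flag_contaminants(annotated)
        diag = evalue_diagnostic(annotated)
        outputs: dict[str, str] = {}
        outputs["annotation"] = str(_write("annotation.tsv", lambda p: write_annotation(annotated, p)))
        outputs["contamination"] = str(
            _write(
                "contamination_summary.tsv",
                lambda p: contamination.to_frame().to_csv(p, sep="\t", index=False),
            )
        )

        stage_name = "diversity"
        clusterable = [a for a in clean if a.best_hit is not None]
        clusters = cluster_by_subject(clusterable)
        div = diversity_table(clusters, libraries, config.stages)
        fam = family_table(clusters, libraries, config.stages)
        audit = cluster_audit(clusters)
        outputs["diversity"] = str(_write("diversity_table.tsv", div.to_tsv))
        outputs["family"] = str(
            _write("family_table.tsv", lambda p: fam.to_csv(p, sep="\t"))
        )
        outputs["audit"] = str(
            _write("cluster_audit.tsv", lambda p: audit.to_csv(p, sep="\t", index=False))
        )

        stage_name = "expression"
        if libraries is not None:
            fam_expr = expression_profiles(clusters, libraries, "family", config.stages)
            cat_expr = expression_profiles(clusters, libraries, "category", config.stages)
            outputs["expression_family"] = str(
                _write("expression_family.tsv", lambda p: fam_expr.to_csv(p, sep="\t", index=False))
            )
            outputs["expression_category"] = str(
                _write(
                    "expression_category.tsv", lambda p: cat_expr.to_csv(p, sep="\t", index=False)
                )
            )

        stage_name = "summary"
        by_category = {
            c: int(div.table.loc[ALL_STAGES, c]) for c in CATEGORIES
        }
        summary = RunSummary(
            n_contigs=len(contigs),
            n_hits=len(hits),
            n_significant_contigs=contamination.n_with_significant_hit,
            fraction_e_le_1e5=diag,
            removed_fractions={
                k: contamination.fraction_of_hits(k) for k in ("bacteria", "plant", "fungi")
            },
            n_removed=contamination.n_removed,
            n_detox_genes=int(div.table.loc[ALL_STAGES, "total"]),
            detox_genes_by_category=by_category,
            outputs=outputs,
        )
        log.info(
            "pipeline done: %d contigs, %d significant, %d detox genes",
            summary.n_contigs,
            summary.n_significant_contigs,
            summary.n_detox_genes,
        )
        return summary
    except DetoxcatError as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise type(exc)(f"pipeline stage '{stage_name}' failed: {exc}") from exc
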