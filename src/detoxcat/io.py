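"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* contig FASTA (Biopython ``SeqIO``); the library stage of origin may be
  embedded in the record description as a ``stage=<label>`` token
* similarity-hit tables: tab-separated, BLAST tabular (outfmt 6) core columns
  plus subject length / kingdom / description extensions
* per-stage read counts: long-format TSV ``contig_id  stage  reads`` with an
  optional ``__total__`` row per stage carrying the declared total mapped reads
* per-contig annotation tables (written by the annotation stage, read back by
  the diversity and expression stages)

All readers validate and reject malformed input rather than silently coercing
it; writers canonicalize column order so that write-then-read is the identity
on valid data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ParseError, SchemaError, ValidationError

#: The eight life stages / castes sampled in the B. huntii study, in report order.
DEFAULT_STAGES: tuple[str, ...] = (
    "egg",
    "early_instar",
    "late_instar",
    "pupa",
    "adult_male",
    "adult_worker",
    "diapausing_queen",
    "egglaying_queen",
)

KINGDOMS = ("animal", "bacteria", "plant", "fungi", "unknown")
CONTAMINANT_KINGDOMS = ("bacteria", "plant", "fungi")

#: Canonical hit-table column order (outfmt-6 core + extensions).
HIT_COLUMNS = (
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "evalue",
    "bitscore",
    "slen",
    "skingdom",
    "sdesc",
)

#: Sentinel contig id for the optional declared-total row in count tables.
TOTAL_ROW_ID = "__total__"


def normalize_kingdom(value: str | None) -> str:
    """Map a free-text kingdom label onto the internal enum (case-insensitive).

    Unrecognized or missing labels become ``"unknown"``.
    """
    if value is None:
        return "unknown"
    v = str(value).strip().lower()
    if v in ("animal", "animalia", "metazoa"):
        return "animal"
    if v in ("bacteria", "bacterial", "prokaryote"):
        return "bacteria"
    if v in ("plant", "plantae", "viridiplantae"):
        return "plant"
    if v in ("fungi", "fungal", "fungus"):
        return "fungi"
    return "unknown"


@dataclass(frozen=True)
class Contig:
    """An assembled contig (or singleton) with optional stage provenance."""

    contig_id: str
    length_bp: int
    stage: str | None = None
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError(f"Contig {self.contig_id}: length_bp must be positive")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise ValidationError(
                f"Contig {self.contig_id}: length_bp={self.length_bp} does not match "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class Hit:
    """One local-similarity match of a contig (query) to a reference gene (subject)."""

    query_id: str
    subject_accession: str
    percent_identity: float
    alignment_length_bp: int
    evalue: float
    bit_score: float
    subject_length_bp: int
    subject_kingdom: str = "unknown"
    subject_description: str = ""

    def __post_init__(self) -> None:
        if self.evalue < 0 or not math.isfinite(self.evalue):
            raise ValidationError(f"Hit {self.query_id}->{self.subject_accession}: evalue must be >= 0")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValidationError(
                f"Hit {self.query_id}->{self.subject_accession}: percent_identity out of [0, 100]"
            )
        if self.alignment_length_bp <= 0:
            raise ValidationError(
                f"Hit {self.query_id}->{self.subject_accession}: alignment_length_bp must be positive"
            )
        if self.subject_length_bp <= 0:
            raise ValidationError(
                f"Hit {self.query_id}->{self.subject_accession}: subject_length_bp must be positive"
            )
        if self.subject_kingdom not in KINGDOMS:
            raise ValidationError(
                f"Hit {self.query_id}->{self.subject_accession}: unknown kingdom "
                f"{self.subject_kingdom!r}"
            )


@dataclass
class StageLibrary:
    """Per-stage mapped-read counts for every contig, plus the library total."""

    stage: str
    counts: dict[str, int] = field(default_factory=dict)
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        for cid, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"Stage {self.stage}: negative read count for {cid}")
        total = sum(self.counts.values())
        if self.total_mapped_reads == 0:
            self.total_mapped_reads = total
        elif self.total_mapped_reads != total:
            raise ValidationError(
                f"Stage {self.stage}: declared total_mapped_reads={self.total_mapped_reads} "
                f"!= sum of counts {total}"
            )
        if self.total_mapped_reads <= 0:
            raise ValidationError(f"Stage {self.stage}: total_mapped_reads must be positive")

    def reads(self, contig_id: str) -> int:
        """Reads mapped to ``contig_id`` in this library; absent contigs count 0."""
        return self.counts.get(contig_id, 0)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _stage_from_description(description: str, token: str) -> str | None:
    for word in description.split():
        if word.startswith(token):
            return word[len(token):]
    return None


def read_fasta(path: str | Path, stage: str | None = None, stage_token: str = "stage=") -> list[Contig]:
    """Read contigs from FASTA.

    The stage of origin is taken from a ``stage=<label>`` token in the record
    description when present, or from the ``stage`` argument otherwise.
    """
    path = Path(path)
    contigs: list[Contig] = []
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(f"{path}: empty sequence for record {record.id!r}")
            rec_stage = _stage_from_description(record.description, stage_token) or stage
            contigs.append(
                Contig(contig_id=record.id, length_bp=len(seq), stage=rec_stage, sequence=seq)
            )
    except ValueError as exc:  # Biopython signals malformed FASTA with ValueError
        raise ParseError(f"{path}: {exc}") from exc
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path) -> None:
    """Write contigs as FASTA, embedding stage provenance as a ``stage=`` token."""
    records = []
    for c in contigs:
        if c.sequence is None:
            raise ValidationError(f"Contig {c.contig_id}: cannot write FASTA without a sequence")
        desc = f"stage={c.stage}" if c.stage else ""
        records.append(SeqRecord(Seq(c.sequence), id=c.contig_id, description=desc))
    SeqIO.write(records, str(Path(path)), "fasta")


# ---------------------------------------------------------------------------
# Hit tables
# ---------------------------------------------------------------------------

def read_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Read an ``accession<TAB>kingdom`` map used when hit tables lack skingdom."""
    df = pd.read_csv(path, sep="\t", header=None, names=["accession", "kingdom"], dtype=str)
    return {str(a): normalize_kingdom(k) for a, k in zip(df["accession"], df["kingdom"])}


def read_hits(path: str | Path, taxonomy_map: Mapping[str, str] | None = None) -> list[Hit]:
    """Read a tab-separated hit table with the canonical columns.

    ``skingdom`` may be omitted if a ``taxonomy_map`` provides kingdoms;
    ``sdesc`` may be omitted (empty descriptions). Duplicate (query, subject)
    rows are retained — multiple HSPs are legitimate.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    optional = {"skingdom", "sdesc"} if taxonomy_map is not None else {"sdesc"}
    for col in HIT_COLUMNS:
        if col not in df.columns and col not in optional:
            raise SchemaError(f"{path}: missing required column {col!r}")
    hits: list[Hit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        def _num(col: str, cast):
            raw = getattr(row, col)
            try:
                return cast(raw)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path} line {i}: non-numeric {col} value {raw!r}") from exc

        accession = str(row.sseqid)
        if taxonomy_map is not None and "skingdom" not in df.columns:
            kingdom = taxonomy_map.get(accession, "unknown")
        else:
            kingdom = normalize_kingdom(getattr(row, "skingdom"))
        hits.append(
            Hit(
                query_id=str(row.qseqid),
                subject_accession=accession,
                percent_identity=_num("pident", float),
                alignment_length_bp=int(_num("length", float)),
                evalue=_num("evalue", float),
                bit_score=_num("bitscore", float),
                subject_length_bp=int(_num("slen", float)),
                subject_kingdom=kingdom,
                subject_description=str(getattr(row, "sdesc", "")),
            )
        )
    return hits


def hits_to_frame(hits: Sequence[Hit]) -> pd.DataFrame:
    """Represent hits as a DataFrame in canonical column order."""
    return pd.DataFrame(
        {
            "qseqid": [h.query_id for h in hits],
            "sseqid": [h.subject_accession for h in hits],
            "pident": [h.percent_identity for h in hits],
            "length": [h.alignment_length_bp for h in hits],
            "evalue": [h.evalue for h in hits],
            "bitscore": [h.bit_score for h in hits],
            "slen": [h.subject_length_bp for h in hits],
            "skingdom": [h.subject_kingdom for h in hits],
            "sdesc": [h.subject_description for h in hits],
        },
        columns=list(HIT_COLUMNS),
    )


def write_hits(hits: Sequence[Hit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Read-count tables
# ---------------------------------------------------------------------------

def read_counts(path: str | Path) -> list[StageLibrary]:
    """Read long-format per-stage read counts and group them into libraries.

    An optional row with contig id ``__total__`` declares the stage's total
    mapped reads; it must agree with the column sum or loading fails.
    Contigs absent from a stage simply have 0 reads there (zero-fill on query).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "stage": str})
    for col in ("contig_id", "stage", "reads"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["reads"]):
        raise ParseError(f"{path}: non-numeric values in 'reads' column")
    if (df["reads"] < 0).any():
        bad = df.loc[df["reads"] < 0].iloc[0]
        raise ValidationError(f"{path}: negative read count for contig {bad['contig_id']!r}")

    libraries: list[StageLibrary] = []
    for stage, grp in df.groupby("stage", sort=True):
        declared = grp.loc[grp["contig_id"] == TOTAL_ROW_ID, "reads"]
        body = grp.loc[grp["contig_id"] != TOTAL_ROW_ID]
        counts = {str(c): int(n) for c, n in zip(body["contig_id"], body["reads"])}
        total = int(declared.iloc[0]) if len(declared) else 0
        libraries.append(StageLibrary(stage=str(stage), counts=counts, total_mapped_reads=total))
    return libraries


def write_counts(libraries: Iterable[StageLibrary], path: str | Path, totals_row: bool = True) -> None:
    rows: list[tuple[str, str, int]] = []
    for lib in libraries:
        for cid in sorted(lib.counts):
            rows.append((cid, lib.stage, lib.counts[cid]))
        if totals_row:
            rows.append((TOTAL_ROW_ID, lib.stage, lib.total_mapped_reads))
    pd.DataFrame(rows, columns=["contig_id", "stage", "reads"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation tables (pipeline intermediate)
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "contig_id",
    "length_bp",
    "stage",
    "sseqid",
    "pident",
    "align_length",
    "evalue",
    "bitscore",
    "slen",
    "skingdom",
    "sdesc",
    "category",
    "family",
    "subfamily",
    "contaminant",
    "sequence",
)


def write_annotation(annotated, path: str | Path) -> None:
    """Write per-contig best-hit annotation (one row per contig, hit fields inline)."""
    rows = []
    for a in annotated:
        h = a.best_hit
        rows.append(
            {
                "contig_id": a.contig.contig_id,
                "length_bp": a.contig.length_bp,
                "stage": a.contig.stage or "",
                "sseqid": h.subject_accession if h else "",
                "pident": h.percent_identity if h else "",
                "align_length": h.alignment_length_bp if h else "",
                "evalue": h.evalue if h else "",
                "bitscore": h.bit_score if h else "",
                "slen": h.subject_length_bp if h else "",
                "skingdom": h.subject_kingdom if h else "",
                "sdesc": h.subject_description if h else "",
                "category": a.category,
                "family": a.family,
                "subfamily": a.subfamily,
                "contaminant": int(a.contaminant),
                "sequence": a.contig.sequence or "",
            }
        )
    pd.DataFrame(rows, columns=list(ANNOTATION_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path):
    """Read an annotation table back into :class:`AnnotatedContig` objects."""
    from .annotation import AnnotatedContig  # deferred: avoid import cycle

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ANNOTATION_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        contig = Contig(
            contig_id=str(row.contig_id),
            length_bp=int(row.length_bp),
            stage=str(row.stage) or None,
            sequence=str(row.sequence) or None,
        )
        best_hit = None
        if row.sseqid:
            best_hit = Hit(
                query_id=contig.contig_id,
                subject_accession=str(row.sseqid),
                percent_identity=float(row.pident),
                alignment_length_bp=int(float(row.align_length)),
                evalue=float(row.evalue),
                bit_score=float(row.bitscore),
                subject_length_bp=int(float(row.slen)),
                subject_kingdom=str(row.skingdom),
                subject_description=str(row.sdesc),
            )
        out.append(
            AnnotatedContig(
                contig=contig,
                best_hit=best_hit,
                category=str(row.category),
                family=str(row.family),
                subfamily=str(row.subfamily),
                contaminant=bool(int(row.contaminant)),
            )
        )
    return out
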