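"""Synthetic reference genes, contigs, hit tables and stage read counts.

The generator emulates the study design the pipeline was built for: eight
life-stage/caste libraries of a bumble bee transcriptome (egg, early instar,
late instar, pupa, adult male, adult worker, diapausing queen, egglaying
queen), a mixture of detoxification genes across the four categories plus
non-detox background genes, a contaminant fraction of bacterial / plant /
fungal sequences, fragmentation of reference genes into contigs (some shorter
than half the gene — the regime where the half-length collapsing rule
matters), and stage-specific expression profiles per enzyme family.

Similarity is simulated directly in the hit table rather than computed by
alignment: the pipeline consumes hit tables, so sequences are uniform-random
nucleotides and realism lives in the E-values, bit scores and subject
descriptions. Every generated contig is resolvable to exactly one true gene
through the returned ground-truth map, so annotation, clustering and
expression stages can be tested for exact recovery.

Defaults are a desk-scale rendition of the study conditions: per-category
detox gene counts in the published 202/109/143/130 proportions (scaled to
20/11/14/13), a 29.8% contaminant fraction split 13.8/12.4/3.6 between
bacteria, plants and fungi, and 100,000 mapped reads per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .annotation import CATEGORIES, NO_CATEGORY
from .errors import ValidationError
from .io import (
    CONTAMINANT_KINGDOMS,
    DEFAULT_STAGES,
    Contig,
    Hit,
    StageLibrary,
    write_counts,
    write_fasta,
    write_hits,
)

#: Description template per enzyme family; chosen so the default keyword
#: ontology classifies each back into exactly its generating family.
FAMILY_DESCRIPTIONS: dict[tuple[str, str], str] = {
    ("cytochrome P450", "CYP4"): "cytochrome P450 CYP4G15",
    ("cytochrome P450", "CYP6"): "cytochrome P450 CYP6AS5",
    ("cytochrome P450", ""): "cytochrome P450 CYP9Q3",
    ("aldehyde dehydrogenase", ""): "aldehyde dehydrogenase",
    ("alcohol dehydrogenase", ""): "alcohol dehydrogenase class-3",
    ("catalase", ""): "catalase",
    ("dehalogenase", ""): "haloacid dehalogenase",
    ("hydroxylase", ""): "tyrosine hydroxylase",
    ("oxidoreductase", ""): "NAD(P)H oxidoreductase",
    ("peroxidase", ""): "glutathione peroxidase",
    ("superoxide dismutase", ""): "superoxide dismutase [Cu-Zn]",
    ("thioredoxin/glutaredoxin", ""): "thioredoxin-2",
    ("glutathione S-transferase", "sigma-GST"): "glutathione S-transferase sigma class",
    ("glutathione S-transferase", "epsilon-GST"): "glutathione S-transferase epsilon class",
    ("glutathione S-transferase", ""): "glutathione S-transferase omega class",
    ("UDP-glucuronosyltransferase", ""): "UDP-glucuronosyltransferase 2B",
    ("acetyltransferase", ""): "arylamine N-acetyltransferase",
    ("acyltransferase", ""): "diacylglycerol O-acyltransferase",
    ("CoA transferase", ""): "succinyl-CoA transferase",
    ("formyltransferase", ""): "methionyl-tRNA formyltransferase",
    ("glycosyltransferase", ""): "glycosyltransferase family 1 protein",
    ("methyltransferase", ""): "juvenile hormone acid methyltransferase",
    ("phosphotransferase", ""): "phosphotransferase enzyme family protein",
    ("sulfotransferase", ""): "sulfotransferase 1C",
    ("transaminase", ""): "alanine aminotransferase",
    ("carboxylesterase/esterase", ""): "carboxylesterase clade E",
    ("acid/alkaline phosphatase", ""): "alkaline phosphatase 4",
    ("amidase", ""): "fatty acid amide hydrolase amidase",
    ("aminopeptidase", ""): "aminopeptidase N",
    ("cyclohydrolase", ""): "GTP cyclohydrolase 1",
    ("amylase", ""): "alpha-amylase",
    ("glucuronidase", ""): "beta-glucuronidase",
    ("glycosidase", ""): "beta-glucosidase",
    ("glycosylase", ""): "uracil-DNA glycosylase",
    ("nitrilase", ""): "nitrilase homolog 1",
    ("phosphodiesterase", ""): "cyclic nucleotide phosphodiesterase",
    ("phosphohydrolase", ""): "nucleoside triphosphate phosphohydrolase",
    ("ABC transporter", ""): "ABC transporter G family member 20",
    ("cadherin", ""): "cadherin-like protein",
    ("heat shock protein", ""): "heat shock protein 70",
    ("isomerase", ""): "protein disulfide isomerase",
    ("lyase", ""): "hydroxynitrile lyase",
}

#: Families drawn per category (with optional subfamily draw weights).
_CATEGORY_FAMILIES: dict[str, list[tuple[str, str]]] = {
    "oxidation_reduction": [
        ("cytochrome P450", "CYP6"),
        ("cytochrome P450", "CYP4"),
        ("cytochrome P450", ""),
        ("aldehyde dehydrogenase", ""),
        ("alcohol dehydrogenase", ""),
        ("catalase", ""),
        ("dehalogenase", ""),
        ("hydroxylase", ""),
        ("oxidoreductase", ""),
        ("peroxidase", ""),
        ("superoxide dismutase", ""),
        ("thioredoxin/glutaredoxin", ""),
    ],
    "conjugation": [
        ("glutathione S-transferase", "sigma-GST"),
        ("glutathione S-transferase", ""),
        ("UDP-glucuronosyltransferase", ""),
        ("acetyltransferase", ""),
        ("acyltransferase", ""),
        ("CoA transferase", ""),
        ("formyltransferase", ""),
        ("glycosyltransferase", ""),
        ("methyltransferase", ""),
        ("phosphotransferase", ""),
        ("sulfotransferase", ""),
        ("transaminase", ""),
    ],
    "hydrolysis": [
        ("carboxylesterase/esterase", ""),
        ("acid/alkaline phosphatase", ""),
        ("amidase", ""),
        ("aminopeptidase", ""),
        ("cyclohydrolase", ""),
        ("amylase", ""),
        ("glucuronidase", ""),
        ("glycosidase", ""),
        ("glycosylase", ""),
        ("nitrilase", ""),
        ("phosphodiesterase", ""),
        ("phosphohydrolase", ""),
    ],
    "other": [
        ("ABC transporter", ""),
        ("cadherin", ""),
        ("heat shock protein", ""),
        ("isomerase", ""),
        ("lyase", ""),
    ],
}

#: Background (non-detox) gene descriptions; none matches an ontology rule.
BACKGROUND_DESCRIPTIONS = (
    "ribosomal protein L4",
    "elongation factor 1-alpha",
    "actin",
    "beta-tubulin",
    "histone H3",
    "ATP synthase subunit beta",
    "vitellogenin",
    "myosin heavy chain",
    "cytochrome c oxidase subunit I",
    "40S ribosomal protein S3",
)


def default_expression_profile() -> dict[tuple[str, str], float]:
    """Stage x family multipliers emulating the reported expression patterns.

    GSTs high in immatures (especially pupae) but low in eggs; oxidoreductases
    and nitrilases high in late instars; glycosidases high in adult workers
    and the egglaying queen; heat shock proteins high in eggs and queens and
    low in males. Unlisted (stage, family) pairs default to 1.0.
    """
    return {
        ("pupa", "glutathione S-transferase"): 4.0,
        ("early_instar", "glutathione S-transferase"): 2.5,
        ("late_instar", "glutathione S-transferase"): 2.5,
        ("egg", "glutathione S-transferase"): 0.4,
        ("late_instar", "oxidoreductase"): 3.0,
        ("late_instar", "nitrilase"): 3.0,
        ("early_instar", "nitrilase"): 2.0,
        ("adult_worker", "glycosidase"): 3.0,
        ("egglaying_queen", "glycosidase"): 3.0,
        ("egg", "heat shock protein"): 3.0,
        ("diapausing_queen", "heat shock protein"): 3.0,
        ("egglaying_queen", "heat shock protein"): 3.0,
        ("adult_male", "heat shock protein"): 0.5,
        ("egglaying_queen", "cytochrome P450"): 2.0,
        ("late_instar", "cytochrome P450"): 1.8,
    }


def _default_category_counts() -> dict[str, int]:
    return {
        "oxidation_reduction": 20,
        "conjugation": 11,
        "hydrolysis": 14,
        "other": 13,
        NO_CATEGORY: 20,
    }


def _default_kingdom_weights() -> dict[str, float]:
    # contaminant split in the published proportions 13.8 : 12.4 : 3.6
    return {"bacteria": 13.8 / 29.8, "plant": 12.4 / 29.8, "fungi": 3.6 / 29.8}


@dataclass(frozen=True)
class ReferenceGene:
    """A simulated reference-database gene (the subject of similarity hits)."""

    accession: str
    length_bp: int
    kingdom: str
    category: str
    family: str = ""
    subfamily: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.length_bp < 100:
            raise ValidationError(f"gene {self.accession}: length_bp must be >= 100")

    @property
    def is_contaminant(self) -> bool:
        return self.kingdom in CONTAMINANT_KINGDOMS


@dataclass
class SimulationParams:
    """Everything the four generators need; validated before use."""

    n_genes_per_category: dict[str, int] = field(default_factory=_default_category_counts)
    contaminant_fraction: float = 0.298
    contaminant_kingdom_weights: dict[str, float] = field(default_factory=_default_kingdom_weights)
    stages: tuple[str, ...] = DEFAULT_STAGES
    fragmentation_rate: float = 2.0
    short_fragment_prob: float = 0.5
    read_depth_per_stage: Mapping[str, int] | int = 100_000
    expression_profile: dict[tuple[str, str], float] = field(
        default_factory=default_expression_profile
    )
    dispersion: float = 0.2
    decoy_rate: float = 1.0
    weak_hit_prob: float = 0.07
    gene_length_range: tuple[int, int] = (400, 3000)
    seed: int = 0

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    def depth(self, stage: str) -> int:
        if isinstance(self.read_depth_per_stage, Mapping):
            return int(self.read_depth_per_stage[stage])
        return int(self.read_depth_per_stage)

    def validate(self) -> None:
        if not self.n_genes_per_category:
            raise ValidationError("n_genes_per_category: must be non-empty")
        for cat, n in self.n_genes_per_category.items():
            if cat not in CATEGORIES and cat != NO_CATEGORY:
                raise ValidationError(f"n_genes_per_category: unknown category {cat!r}")
            if n <= 0:
                raise ValidationError(f"n_genes_per_category[{cat!r}]: counts must be positive")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValidationError("contaminant_fraction: must be in [0, 1)")
        if not self.stages:
            raise ValidationError("stages: must be non-empty")
        if self.fragmentation_rate < 1.0:
            raise ValidationError("fragmentation_rate: mean contigs per gene must be >= 1")
        if not 0.0 <= self.short_fragment_prob <= 1.0:
            raise ValidationError("short_fragment_prob: must be in [0, 1]")
        for stage in self.stages:
            if self.depth(stage) <= 0:
                raise ValidationError(f"read_depth_per_stage[{stage!r}]: must be positive")
        for (stage, fam), mult in self.expression_profile.items():
            if mult < 0:
                raise ValidationError(f"expression_profile[{(stage, fam)!r}]: must be >= 0")
        if self.dispersion < 0:
            raise ValidationError("dispersion: must be >= 0")
        if self.decoy_rate < 0:
            raise ValidationError("decoy_rate: must be >= 0")
        lo, hi = self.gene_length_range
        if lo < 100 or hi < lo:
            raise ValidationError("gene_length_range: need 100 <= lo <= hi")

    def multiplier(self, stage: str, family: str) -> float:
        return self.expression_profile.get((stage, family), 1.0)

    def _rng(self, stream: int) -> np.random.Generator:
        # independent, order-insensitive substream per generator
        return np.random.default_rng([self.seed, stream])


def _apportion(total: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of `total` among weighted classes."""
    keys = list(weights)
    w = np.array([weights[k] for k in keys], dtype=float)
    if w.sum() <= 0:
        raise ValidationError("contaminant_kingdom_weights: weights must sum to > 0")
    quota = total * w / w.sum()
    counts = np.floor(quota).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quota - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(keys, counts.tolist()))


def generate_reference_set(params: SimulationParams) -> list[ReferenceGene]:
    """Generate the reference gene set with exact per-category counts.

    ``round(contaminant_fraction * N)`` genes of the full set are assigned a
    non-animal kingdom (split among bacteria/plants/fungi by the configured
    weights, largest-remainder rounding), emulating contaminant sequences in
    the reference database that detox-like contigs can match.
    """
    params.validate()
    rng = params._rng(0)
    lo, hi = params.gene_length_range

    genes: list[ReferenceGene] = []
    order = [c for c in (*CATEGORIES, NO_CATEGORY) if c in params.n_genes_per_category]
    i = 0
    for category in order:
        n = params.n_genes_per_category[category]
        for _ in range(n):
            i += 1
            accession = f"G{i:05d}"
            length = int(rng.integers(lo, hi + 1))
            if category == NO_CATEGORY:
                desc = BACKGROUND_DESCRIPTIONS[int(rng.integers(len(BACKGROUND_DESCRIPTIONS)))]
                family, subfamily = "", ""
            else:
                choices = _CATEGORY_FAMILIES[category]
                family, subfamily = choices[int(rng.integers(len(choices)))]
                desc = FAMILY_DESCRIPTIONS[(family, subfamily)]
            genes.append(
                ReferenceGene(
                    accession=accession,
                    length_bp=length,
                    kingdom="animal",
                    category=category,
                    family=family,
                    subfamily=subfamily,
                    description=desc,
                )
            )

    n_cont = round(params.contaminant_fraction * len(genes))
    if n_cont:
        by_kingdom = _apportion(n_cont, params.contaminant_kingdom_weights)
        chosen = rng.choice(len(genes), size=n_cont, replace=False)
        kingdoms = [k for k, n in by_kingdom.items() for _ in range(n)]
        for idx, kingdom in zip(sorted(chosen.tolist()), kingdoms):
            g = genes[idx]
            genes[idx] = ReferenceGene(
                accession=g.accession,
                length_bp=g.length_bp,
                kingdom=kingdom,
                category=g.category,
                family=g.family,
                subfamily=g.subfamily,
                description=g.description,
            )
    return genes


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def simulate_contigs(
    genes: Sequence[ReferenceGene], params: SimulationParams
) -> tuple[list[Contig], dict[str, str]]:
    """Fragment each gene into contigs; return contigs and the true contig->gene map.

    Per gene the number of contigs is ``1 + Poisson(fragmentation_rate - 1)``
    (so a rate of 1 yields exactly one contig per gene). With probability
    ``short_fragment_prob`` a contig is shorter than half its gene; otherwise
    it is at least half the gene length. The stage of origin recorded in the
    FASTA header is drawn per contig, weighted by the gene family's stage
    profile.
    """
    if not genes:
        raise ValidationError("genes: must be non-empty")
    params.validate()
    rng = params._rng(1)
    stages = list(params.stages)

    contigs: list[Contig] = []
    contig_map: dict[str, str] = {}
    i = 0
    for gene in genes:
        n_contigs = 1 + int(rng.poisson(params.fragmentation_rate - 1.0))
        stage_weights = np.array(
            [params.multiplier(s, gene.family) for s in stages], dtype=float
        )
        if stage_weights.sum() <= 0:
            stage_weights = np.ones(len(stages))
        stage_weights = stage_weights / stage_weights.sum()
        half_floor = (gene.length_bp - 1) // 2  # longest length strictly < L/2
        for _ in range(n_contigs):
            i += 1
            cid = f"CTG{i:06d}"
            if rng.random() < params.short_fragment_prob:
                lo = max(100, gene.length_bp // 10)
                length = int(rng.integers(min(lo, half_floor), half_floor + 1))
            else:
                length = int(rng.integers((gene.length_bp + 1) // 2, gene.length_bp + 1))
            stage = stages[int(rng.choice(len(stages), p=stage_weights))]
            contigs.append(
                Contig(
                    contig_id=cid,
                    length_bp=length,
                    stage=stage,
                    sequence=_random_sequence(rng, length),
                )
            )
            contig_map[cid] = gene.accession
    return contigs, contig_map


def simulate_hits(
    contigs: Sequence[Contig],
    contig_map: Mapping[str, str],
    genes: Sequence[ReferenceGene],
    params: SimulationParams,
) -> list[Hit]:
    """Emit a hit table in which every contig's true gene is its best hit.

    The true hit always has the strictly smallest E-value (and the largest
    bit score) among the contig's rows, and is always significant
    (E <= 0.001); a small configured share of true hits falls in the weaker
    (1e-5, 1e-3] band, mirroring the observation that more than 93% of real
    matches had E <= 1e-05. Decoy hits to other genes are strictly worse and
    may be non-significant.
    """
    params.validate()
    by_accession = {g.accession: g for g in genes}
    for c in contigs:
        if c.contig_id not in contig_map:
            raise ValidationError(f"contig {c.contig_id} missing from contig_map")
        if contig_map[c.contig_id] not in by_accession:
            raise ValidationError(
                f"contig {c.contig_id}: unknown gene {contig_map[c.contig_id]!r}"
            )
    rng = params._rng(2)
    accessions = [g.accession for g in genes]

    hits: list[Hit] = []
    for contig in contigs:
        gene = by_accession[contig_map[contig.contig_id]]
        if rng.random() < params.weak_hit_prob:
            exponent = rng.uniform(3.0, 5.0)  # E in (1e-5, 1e-3]
        else:
            exponent = rng.uniform(5.0, 40.0)
        evalue = 10.0 ** (-exponent)
        bitscore = round(2.0 * exponent + rng.uniform(40.0, 60.0), 1)
        align_len = max(30, int(contig.length_bp * rng.uniform(0.6, 0.95)))
        hits.append(
            Hit(
                query_id=contig.contig_id,
                subject_accession=gene.accession,
                percent_identity=round(float(rng.uniform(78.0, 99.5)), 1),
                alignment_length_bp=align_len,
                evalue=evalue,
                bit_score=bitscore,
                subject_length_bp=gene.length_bp,
                subject_kingdom=gene.kingdom,
                subject_description=gene.description,
            )
        )
        n_decoys = int(rng.poisson(params.decoy_rate)) if len(genes) > 1 else 0
        for _ in range(n_decoys):
            decoy = by_accession[accessions[int(rng.integers(len(accessions)))]]
            if decoy.accession == gene.accession:
                continue
            decoy_evalue = min(10.0, evalue * 10.0 ** rng.uniform(1.0, 8.0))
            hits.append(
                Hit(
                    query_id=contig.contig_id,
                    subject_accession=decoy.accession,
                    percent_identity=round(float(rng.uniform(40.0, 75.0)), 1),
                    alignment_length_bp=max(30, int(align_len * rng.uniform(0.3, 0.8))),
                    evalue=decoy_evalue,
                    bit_score=round(max(20.0, bitscore - rng.uniform(10.0, 40.0)), 1),
                    subject_length_bp=decoy.length_bp,
                    subject_kingdom=decoy.kingdom,
                    subject_description=decoy.description,
                )
            )
    return hits


def simulate_read_counts(
    contigs: Sequence[Contig],
    contig_map: Mapping[str, str],
    genes: Sequence[ReferenceGene],
    params: SimulationParams,
) -> list[StageLibrary]:
    """Draw per-stage per-contig counts from a negative binomial.

    The mean for contig *c* in stage *s* is
    ``depth(s) * length_c * multiplier(s, family_c) / sum_c length_c`` — i.e.
    length-proportional at nominal depth with unit multipliers, so doubling a
    family's multiplier doubles its expected count. Each library's
    ``total_mapped_reads`` is the realized sum of its counts. With dispersion
    d > 0 the variance is ``m + d m^2`` (d = 0 falls back to Poisson).
    """
    params.validate()
    by_accession = {g.accession: g for g in genes}
    rng = params._rng(3)
    lengths = np.array([c.length_bp for c in contigs], dtype=float)
    baseline = lengths.sum()
    libraries: list[StageLibrary] = []
    for stage in params.stages:
        depth = params.depth(stage)
        counts: dict[str, int] = {}
        for contig, length in zip(contigs, lengths):
            family = by_accession[contig_map[contig.contig_id]].family
            mean = depth * length * params.multiplier(stage, family) / baseline
            if mean <= 0:
                n = 0
            elif params.dispersion > 0:
                shape = 1.0 / params.dispersion
                p = shape / (shape + mean)
                n = int(rng.negative_binomial(shape, p))
            else:
                n = int(rng.poisson(mean))
            counts[contig.contig_id] = n
        libraries.append(StageLibrary(stage=stage, counts=counts))
    return libraries


@dataclass
class SimulatedDataset:
    """One complete synthetic experiment with its ground truth."""

    params: SimulationParams
    genes: list[ReferenceGene]
    contigs: list[Contig]
    contig_map: dict[str, str]
    hits: list[Hit]
    libraries: list[StageLibrary]

    def gene(self, accession: str) -> ReferenceGene:
        return next(g for g in self.genes if g.accession == accession)

    def true_category_counts(self, clean_only: bool = True) -> dict[str, int]:
        """Ground-truth detox gene count per category (animal genes by default)."""
        counts = {c: 0 for c in CATEGORIES}
        covered = set(self.contig_map.values())
        for g in self.genes:
            if g.category == NO_CATEGORY or g.accession not in covered:
                continue
            if clean_only and g.is_contaminant:
                continue
            counts[g.category] += 1
        return counts

    def true_contaminant_contig_fractions(self) -> dict[str, float]:
        """Per-kingdom fraction of contigs whose true gene is a contaminant."""
        by_accession = {g.accession: g for g in self.genes}
        total = len(self.contigs)
        frac = {k: 0.0 for k in CONTAMINANT_KINGDOMS}
        for c in self.contigs:
            g = by_accession[self.contig_map[c.contig_id]]
            if g.is_contaminant:
                frac[g.kingdom] += 1.0 / total
        return frac

    def manifest(self) -> dict:
        return {
            "seed": self.params.seed,
            "stages": list(self.params.stages),
            "n_genes": len(self.genes),
            "n_contigs": len(self.contigs),
            "genes": [
                {
                    "accession": g.accession,
                    "length_bp": g.length_bp,
                    "kingdom": g.kingdom,
                    "category": g.category,
                    "family": g.family,
                    "subfamily": g.subfamily,
                }
                for g in self.genes
            ],
            "contig_map": dict(self.contig_map),
            "true_category_counts": self.true_category_counts(),
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write contig FASTA, hit TSV, count TSV and ground-truth YAML manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "contigs": outdir / "contigs.fasta",
            "hits": outdir / "hits.tsv",
            "counts": outdir / "counts.tsv",
            "manifest": outdir / "truth.yaml",
        }
        write_fasta(self.contigs, paths["contigs"])
        write_hits(self.hits, paths["hits"])
        write_counts(self.libraries, paths["counts"])
        with open(paths["manifest"], "w") as fh:
            yaml.safe_dump(self.manifest(), fh, sort_keys=True)
        return paths


def simulate_dataset(params: SimulationParams | None = None) -> SimulatedDataset:
    """Run all four generators with one parameter set (fully seeded)."""
    params = params or SimulationParams()
    genes = generate_reference_set(params)
    contigs, contig_map = simulate_contigs(genes, params)
    hits = simulate_hits(contigs, contig_map, genes, params)
    libraries = simulate_read_counts(contigs, contig_map, genes, params)
    return SimulatedDataset(
        params=params,
        genes=genes,
        contigs=contigs,
        contig_map=contig_map,
        hits=hits,
        libraries=libraries,
    )
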