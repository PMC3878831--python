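# Methods

## The procedure

The pipeline reconstructs a detoxification-gene catalogue from three inputs:
assembled contigs (FASTA), a tabular similarity search of those contigs
against a reference protein/gene database (BLAST outfmt-6-like TSV with
subject length, kingdom and description columns), and per-stage per-contig
mapped-read counts (long-format TSV). It deliberately consumes the hit table
rather than running an aligner: assembly and searching are upstream tools'
jobs, and taking their tabular output keeps runs reproducible and
download-free.

**Significance and best hit.** A hit is significant when E ≤ t with
t = 0.001 by default; the boundary is inclusive. Each contig is represented
by one best hit: minimal E-value, ties broken by maximal bit score, then by
lexicographically smallest subject accession. The third key exists only to
make the choice a total order, so permuting input rows can never change any
downstream number. The share of best hits at E ≤ 10⁻⁵ is reported as a
diagnostic of match quality but never enforced.

**Contaminant removal.** A contig is a contaminant iff its best hit's
kingdom is bacteria, plant or fungi; lower-ranked hits never veto an animal
best hit. Kingdoms come from an explicit hit-table column or an
accession → kingdom map file, not from a live taxonomy service. Because it
is unstated whether published contamination percentages were computed over
all contigs or only those with significant hits, the summary reports both
denominators.

**Classification.** Categories and families are assigned by an ordered list
of case-insensitive regexes over the best hit's subject description; the
first matching rule wins, and rule order is part of the ontology's contract
(subfamily rules such as `\bcyp6` precede their family rule). A keyword
ontology is a transparent, user-editable stand-in for "identified by
comparison with known detoxification genes"; users with curated accession
lists can express them as patterns or swap in their own table. Contigs with
no significant hit, or no matching rule, carry category `none`: they stay in
the annotation output but are excluded from every detox table, consistent
with counting only hit-identified genes.

**Half-length collapsing rule.** Contigs that differ in sequence but share a
best-hit subject form one cluster. If every distinct member is shorter than
half the subject's length, they are regions of a single gene (count 1);
otherwise each distinct member counts as a separate gene. Identical
sequences are deduplicated first — the rule's premise is contigs that
*differ* in sequence, and the same transcript assembled in two stage
libraries must not count twice. For mixed clusters (members on both sides of
the cut) we apply the rule's "otherwise" branch literally — each distinct
contig is a gene — because the rule names no special case; since short
members could alternatively be read as regions of the long ones, mixed
clusters are flagged (`rule_branch = mixed`) in the per-cluster audit table
so a curator can revisit them. Exactly half the subject length is *not*
"shorter than half". A cluster whose subject length is unknown cannot be
resolved and is an error rather than a guess.

**Diversity tables.** Cell (stage, category) sums inferred gene counts over
clusters of that category with read evidence (>0 reads in any member contig)
in that stage; when no count data are supplied, the member contigs'
library-of-origin labels substitute. The all-stages row counts each gene
once over the union of stages, so it is deliberately *not* the column sum of
the per-stage rows. Row totals always equal the sum of their four category
cells, and `check_table_consistency` verifies exactly that — on pipeline
output and on externally transcribed published tables alike. Family tables
repeat the computation per enzyme family with subfamily sub-rows (CYP4,
CYP6, sigma-GST, epsilon-GST); a sub-row can never exceed its family row
because it counts a subset of the same clusters. Cross-species comparisons
merge externally supplied per-species count tables, zero-filling absent
families.

**Expression.** RPKM per gene is
`reads / (total mapped reads in millions × gene length in kb)`; per group it
is `total group reads / (total mapped reads in millions × mean group gene
length in kb)`. For equal-length genes the group statistic equals the sum of
the member statistics exactly; with unequal lengths it is the published
cumulative definition, not that sum. A fragmented gene's length is the sum
of its distinct member-contig lengths capped at the reference subject's
length — the cap stops a fragmented gene from appearing longer than its
reference, which would deflate its RPKM. A cluster's reads in a stage are
the sum of its member contigs' reads. Values are reported raw, never
log-transformed. No differential-expression testing is attempted: single
pooled libraries per stage admit no replication, so the profiles are
descriptive.

## The synthetic-data generator

The generator emulates the study design, not sequencing physics. Defaults
are the study conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| genes per category | 20 / 11 / 14 / 13 (+20 background) | the published 202/109/143/130 proportions at ~1/10 scale |
| contaminant fraction | 0.298 | published removal total (13.8% bacterial + 12.4% plant + 3.6% fungal) |
| contaminant kingdom split | 13.8 : 12.4 : 3.6 | published per-kingdom removal rates |
| stages | the eight study labels | egg … egglaying queen |
| reads per stage | 100,000 | desk-scale depth; large enough that every expressed contig is detected |
| fragmentation rate | 2.0 contigs/gene | exercises the collapsing rule; `1 + Poisson(rate − 1)` so rate 1 is exactly one contig per gene |
| short-fragment probability | 0.5 | mixes both rule branches by default |
| gene length | uniform 400–3000 bp | typical mRNA range |
| NB dispersion | 0.2 | moderate overdispersion; no count model is prescribed, 0 falls back to Poisson |

Contaminant status is assigned to `round(fraction × N)` genes of the whole
set by largest-remainder apportionment across kingdoms, so contaminant
counts are exact rather than binomial; contaminant genes keep detox-like
descriptions, as real contaminant sequences are detox-similar matches.
Sequences are uniform-random nucleotides and similarity lives entirely in
the generated hit table (the pipeline never aligns), with the true gene
always the strictly best, always-significant hit and decoy hits strictly
worse; about 7% of true hits fall in the weak (10⁻⁵, 10⁻³] band to mirror
the ">93% at E ≤ 10⁻⁵" observation. Stage counts are negative binomial with
mean `depth × contig length × multiplier(stage, family) / Σ lengths`, i.e.
length-proportional at nominal depth with unit multipliers, so doubling a
family's multiplier doubles its expected count; each library's recorded
total is the realized sum (conservation holds by construction). The default
stage × family multipliers encode the reported qualitative patterns (GSTs up
in immatures, especially pupae, low in eggs; nitrilases and oxidoreductases
up in late instars; glycosidases up in adult workers and the egglaying
queen; heat shock proteins up in eggs and queens, down in males).

What the generator does *not* emulate — read-level errors, chimeric or
mis-assembled contigs, hit tables where the true gene is outranked by a
paralog, genes expressed in no stage, and cross-contig multi-mapping —
bounds what passing tests show: they certify the bookkeeping (annotation,
removal, collapsing, normalization) is exact on data satisfying the model's
assumptions, not that annotation of a real assembly is error-free.

Every generator is seeded; each of the four draws from its own
`(seed, stream)` substream, so outputs are byte-identical across reruns and
independent of call order.

## Numerical and design choices

- Recovery is exact, and tested exact, in the two regimes where the
  half-length rule is unambiguous: all fragments short (any fragmentation
  rate), or exactly one ≥-half contig per gene. Between those regimes the
  rule intentionally over-counts genes with both long and short contigs;
  that is the rule's behaviour, not an implementation artifact, and the
  audit table makes it visible.
- Mean read length is rounded half-up (355,789,178 bp / 837,010 reads →
  425 bp); banker's rounding would be surprising in a report.
- Zero-read stages are legitimate, not errors; contigs absent from a count
  table have 0 reads. Malformed input (negative counts, totals rows that
  contradict the column sum, missing columns, non-numeric E-values) is
  rejected, never coerced.
- Pipeline failures remove partially written outputs and name the failed
  stage; inputs are never mutated.
- Problem sizes in the test suite and acceptance script (≤ ~80 genes,
  ≤ ~200 contigs, 10,000 randomized clusters, 1,000 randomized RPKM cases)
  were chosen so the full battery runs in seconds while still covering both
  rule branches, both contamination denominators and all eight stages.

## Known limitations

- Keyword classification inherits the reference database's description
  quality; a hit described only by an accession classifies as `none`.
- The half-length rule cannot distinguish alleles from paralogs among
  multiple long contigs, and its mixed-cluster branch is a convention (see
  above); counts for heavily fragmented genes are upper bounds.
- Stage membership relies on read evidence; a gene expressed below detection
  depth in a stage is absent from that stage's row.
- Cross-species family comparisons merge externally supplied counts as
  given; no orthology calling is attempted.
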