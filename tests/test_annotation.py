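"""Significance filtering, best-hit selection, contaminant removal, classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detoxcat import (
    AnnotatedContig,
    ConfigError,
    Contig,
    FamilyOntology,
    Hit,
    OntologyRule,
    ValidationError,
    annotate,
    classify,
    filter_significant,
    flag_contaminants,
    select_best_hit,
    simulate_dataset,
)
from detoxcat.annotation import assign_best_hits, evalue_diagnostic
from detoxcat.simulate import SimulationParams


def hit(query="C1", subject="G1", evalue=1e-10, bits=100.0, kingdom="animal", desc=""):
    return Hit(
        query_id=query,
        subject_accession=subject,
        percent_identity=90.0,
        alignment_length_bp=200,
        evalue=evalue,
        bit_score=bits,
        subject_length_bp=1000,
        subject_kingdom=kingdom,
        subject_description=desc,
    )


class TestFilterSignificant:
    def test_boundary_evalue_retained(self):
        # the significance rule is "less than or equal to" the threshold
        assert filter_significant([hit(evalue=0.001)], 0.001) == [hit(evalue=0.001)]

    def test_just_above_threshold_removed(self):
        assert filter_significant([hit(evalue=0.0011)], 0.001) == []

    def test_empty_input(self):
        assert filter_significant([], 0.001) == []

    def test_order_stable(self):
        hits = [hit(subject=f"G{i}", evalue=1e-4) for i in range(5)]
        assert filter_significant(hits) == hits

    def test_invalid_threshold(self):
        with pytest.raises(ValidationError):
            filter_significant([], 0.0)


class TestSelectBestHit:
    def test_lowest_evalue_wins(self):
        best = select_best_hit([hit(subject="A", evalue=1e-5), hit(subject="B", evalue=1e-10)])
        assert best.subject_accession == "B"

    def test_tie_broken_by_bit_score_invariant_under_ordering(self):
        hits = [
            hit(subject="A", evalue=1e-8, bits=50.0),
            hit(subject="B", evalue=1e-8, bits=60.0),
            hit(subject="C", evalue=1e-6, bits=90.0),
        ]
        for perm in itertools.permutations(hits):
            assert select_best_hit(list(perm)).subject_accession == "B"

    def test_full_tie_broken_by_accession(self):
        hits = [hit(subject="GB"), hit(subject="GA")]
        for perm in itertools.permutations(hits):
            assert select_best_hit(list(perm)).subject_accession == "GA"

    def test_empty_means_no_hit(self):
        assert select_best_hit([]) is None


class TestFlagContaminants:
    def _annotated(self, kingdoms):
        out = []
        for i, k in enumerate(kingdoms):
            contig = Contig(f"C{i}", 500)
            h = hit(query=f"C{i}", subject=f"G{i}", kingdom=k)
            out.append(AnnotatedContig(contig=contig, best_hit=h, contaminant=k != "animal"))
        return out

    def test_all_animal_nothing_removed(self):
        clean, summary = flag_contaminants(self._annotated(["animal"] * 4))
        assert len(clean) == 4
        assert summary.n_removed == 0
        assert summary.fraction_of_hits("bacteria") == 0.0

    def test_bacterial_fraction(self):
        kingdoms = ["bacteria"] * 3 + ["animal"] * 7
        clean, summary = flag_contaminants(self._annotated(kingdoms))
        assert len(clean) == 7
        assert summary.fraction_of_hits("bacteria") == pytest.approx(0.30)
        assert summary.fraction_of_all("bacteria") == pytest.approx(0.30)

    def test_only_best_hit_decides(self):
        contig = Contig("C1", 500)
        hits = [
            hit(query="C1", subject="GA", evalue=1e-20, kingdom="animal"),
            hit(query="C1", subject="GB", evalue=1e-5, kingdom="bacteria"),
        ]
        annotated = assign_best_hits([contig], hits)
        clean, summary = flag_contaminants(annotated)
        assert len(clean) == 1
        assert summary.n_removed == 0


class TestClassify:
    def test_p450_subfamily(self, ontology):
        assert ontology.classify_description("cytochrome P450 CYP6AS5") == (
            "oxidation_reduction",
            "cytochrome P450",
            "CYP6",
        )

    def test_background_gene_unclassified(self, ontology):
        assert ontology.classify_description("ribosomal protein L4") == ("none", "", "")

    @pytest.mark.parametrize(
        "desc, expected",
        [
            ("glutathione S-transferase sigma class", ("conjugation", "glutathione S-transferase", "sigma-GST")),
            ("glutathione S-transferase", ("conjugation", "glutathione S-transferase", "")),
            ("cytochrome P450 CYP4G15", ("oxidation_reduction", "cytochrome P450", "CYP4")),
            ("beta-glucosidase precursor", ("hydrolysis", "glycosidase", "")),
            ("heat shock protein 70", ("other", "heat shock protein", "")),
            ("alkaline phosphatase 4", ("hydrolysis", "acid/alkaline phosphatase", "")),
        ],
    )
    def test_default_ontology_examples(self, ontology, desc, expected):
        assert ontology.classify_description(desc) == expected

    def test_first_matching_rule_wins(self):
        rules = [
            OntologyRule("p450", "oxidation_reduction", "first"),
            OntologyRule("cytochrome", "oxidation_reduction", "second"),
        ]
        assert FamilyOntology(rules).classify_description("cytochrome p450")[1] == "first"
        flipped = FamilyOntology(rules[::-1])
        assert flipped.classify_description("cytochrome p450")[1] == "second"

    def test_malformed_pattern_is_config_error(self):
        with pytest.raises(ConfigError):
            FamilyOntology([OntologyRule("[unclosed", "other", "x")])

    def test_unknown_category_rejected(self):
        with pytest.raises(ConfigError):
            FamilyOntology([OntologyRule("x", "not_a_category", "x")])

    def test_tsv_and_yaml_loaders_agree(self, tmp_path, ontology):
        tsv = tmp_path / "ont.tsv"
        tsv.write_text("pattern\tcategory\tfamily\tsubfamily\ncatalase\toxidation_reduction\tcatalase\t\n")
        yml = tmp_path / "ont.yaml"
        yml.write_text(
            "- {pattern: catalase, category: oxidation_reduction, family: catalase}\n"
        )
        a = FamilyOntology.from_file(tsv)
        b = FamilyOntology.from_file(yml)
        assert a.classify_description("catalase") == b.classify_description("catalase")

    def test_no_hit_contigs_stay_unclassified(self, ontology):
        a = AnnotatedContig(contig=Contig("C1", 300), best_hit=None)
        (out,) = classify([a], ontology)
        assert out.category == "none"


@settings(max_examples=50, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_permuting_hit_rows_never_changes_assignments(seed):
    """Deterministic tie-breaks make annotation order-insensitive."""
    import random

    p = SimulationParams(
        n_genes_per_category={"oxidation_reduction": 3, "hydrolysis": 3},
        contaminant_fraction=0.2,
        seed=17,
    )
    ds = simulate_dataset(p)
    baseline = annotate(ds.contigs, ds.hits)
    shuffled = list(ds.hits)
    random.Random(seed).shuffle(shuffled)
    assert annotate(ds.contigs, shuffled) == baseline


def test_full_recovery_without_decoys_or_contamination():
    """Every detox contig classifies into its generating family."""
    p = SimulationParams(contaminant_fraction=0.0, decoy_rate=0.0, seed=5)
    ds = simulate_dataset(p)
    by_acc = {g.accession: g for g in ds.genes}
    annotated = annotate(ds.contigs, ds.hits)
    for a in annotated:
        true_gene = by_acc[ds.contig_map[a.contig.contig_id]]
        assert a.best_hit.subject_accession == true_gene.accession
        assert a.category == true_gene.category
        if true_gene.category != "none":
            assert a.family == true_gene.family
            assert a.subfamily == true_gene.subfamily


def test_evalue_diagnostic_reports_fraction():
    contigs = [Contig(f"C{i}", 500) for i in range(4)]
    hits = [
        hit(query="C0", evalue=1e-10),
        hit(query="C1", evalue=1e-8),
        hit(query="C2", evalue=1e-6),
        hit(query="C3", evalue=1e-4),  # significant, but above the 1e-05 band
    ]
    annotated = assign_best_hits(contigs, hits)
    assert evalue_diagnostic(annotated) == pytest.approx(0.75)
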