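"""Contig collapsing (half-length rule), diversity and family tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from detoxcat import (
    ALL_STAGES,
    AnnotatedContig,
    Contig,
    GeneCluster,
    Hit,
    StageLibrary,
    ValidationError,
    cluster_by_subject,
    count_genes,
    diversity_table,
    family_table,
    simulate_dataset,
    species_comparison_table,
)
from detoxcat.annotation import annotate, flag_contaminants
from detoxcat.diversity import cluster_audit, detox_clusters
from detoxcat.simulate import SimulationParams

STAGES = ("egg", "pupa")


def member(contig_id, length, subject="G1", subject_len=1000, sequence=None, stage=None,
           category="oxidation_reduction", family="catalase", subfamily=""):
    contig = Contig(contig_id, length, stage=stage, sequence=sequence)
    h = Hit(
        query_id=contig_id,
        subject_accession=subject,
        percent_identity=90.0,
        alignment_length_bp=min(length, 100),
        evalue=1e-10,
        bit_score=100.0,
        subject_length_bp=subject_len,
        subject_kingdom="animal",
        subject_description=family,
    )
    return AnnotatedContig(contig=contig, best_hit=h, category=category, family=family,
                           subfamily=subfamily)


def make_cluster(subject_len, lengths, sequences=None, **kwargs):
    members = [
        member(f"C{i}", l, subject_len=subject_len,
               sequence=None if sequences is None else sequences[i], **kwargs)
        for i, l in enumerate(lengths)
    ]
    return GeneCluster(
        subject_accession="G1",
        subject_length_bp=subject_len,
        members=members,
        category=kwargs.get("category", "oxidation_reduction"),
        family=kwargs.get("family", "catalase"),
        subfamily=kwargs.get("subfamily", ""),
    )


def brute_force_count(lengths, subject_len):
    """Independent restatement of the collapsing rule on distinct sequences:
    contigs matching the same gene are one gene if each is shorter than half
    the gene's length, otherwise they are different genes (one per contig)."""
    if all(2 * l < subject_len for l in lengths):
        return 1
    return len(lengths)


class TestClusterBySubject:
    def test_three_contigs_two_subjects(self):
        annotated = [
            member("C1", 400, subject="GA"),
            member("C2", 400, subject="GB"),
            member("C3", 400, subject="GA"),
        ]
        clusters = cluster_by_subject(annotated)
        assert [c.subject_accession for c in clusters] == ["GA", "GB"]
        assert [len(c.members) for c in clusters] == [2, 1]

    def test_empty_input(self):
        assert cluster_by_subject([]) == []

    def test_permutation_invariance(self):
        annotated = [member(f"C{i}", 300 + i, subject=f"G{i % 3}") for i in range(9)]
        a = cluster_by_subject(annotated)
        b = cluster_by_subject(annotated[::-1])
        assert [(c.subject_accession, c.contig_ids()) for c in a] == [
            (c.subject_accession, c.contig_ids()) for c in b
        ]

    def test_unhit_contig_rejected(self):
        bad = AnnotatedContig(contig=Contig("C1", 300), best_hit=None)
        with pytest.raises(ValidationError):
            cluster_by_subject([bad])


class TestCountGenes:
    def test_all_short_collapse_to_one_gene(self):
        assert count_genes(make_cluster(1000, [300, 400])) == 1

    def test_all_long_count_as_separate_genes(self):
        assert count_genes(make_cluster(1000, [600, 700])) == 2

    def test_singleton_long_contig(self):
        assert count_genes(make_cluster(1000, [600])) == 1

    def test_mixed_lengths_follow_otherwise_branch(self):
        # one short + one long: the "otherwise" branch counts each contig
        cluster = make_cluster(1000, [300, 600])
        assert count_genes(cluster) == 2
        assert cluster.is_mixed

    def test_boundary_exactly_half_is_not_short(self):
        assert count_genes(make_cluster(1000, [500, 499])) == 2

    def test_identical_sequences_deduplicated_before_counting(self):
        seq = "ACGT" * 150
        cluster = make_cluster(1000, [600, 600], sequences=[seq, seq])
        assert count_genes(cluster) == 1

    def test_missing_subject_length_is_an_error(self):
        cluster = make_cluster(1000, [300])
        cluster.subject_length_bp = 0
        with pytest.raises(ValidationError):
            count_genes(cluster)

    def test_oracle_agreement_on_randomized_clusters(self):
        rng = np.random.default_rng(2024)
        for _ in range(2000):
            subject_len = int(rng.integers(100, 3000))
            n = int(rng.integers(1, 7))
            lengths = rng.integers(50, subject_len + 1, size=n).tolist()
            cluster = make_cluster(subject_len, lengths)
            assert count_genes(cluster) == brute_force_count(lengths, subject_len)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        subject_len=st.integers(100, 4000),
        lengths=st.lists(st.integers(50, 4000), min_size=1, max_size=6),
    )
    def test_count_bounds_and_monotonicity(self, subject_len, lengths):
        lengths = [min(l, subject_len) for l in lengths]
        cluster = make_cluster(subject_len, lengths)
        n = count_genes(cluster)
        assert 1 <= n <= len(lengths)
        # adding a member never decreases the inferred count
        bigger = make_cluster(subject_len, lengths + [min(subject_len, lengths[-1])])
        assert count_genes(bigger) >= n


class TestDiversityTable:
    def _library(self, stage, counts):
        return StageLibrary(stage, counts)

    def test_union_semantics_single_cluster(self):
        cluster = make_cluster(1000, [600, 700])  # 2 genes
        libs = [self._library(s, {"C0": 5, "C1": 3}) for s in STAGES]
        table = diversity_table([cluster], libs, STAGES).table
        assert all(table.loc[s, "oxidation_reduction"] == 2 for s in STAGES)
        assert table.loc[ALL_STAGES, "oxidation_reduction"] == 2
        assert table.loc[ALL_STAGES, "total"] == 2

    def test_no_clusters_all_zero(self):
        table = diversity_table([], None, STAGES).table
        assert int(table.to_numpy().sum()) == 0

    def test_stage_membership_from_read_evidence(self):
        cluster = make_cluster(1000, [600])
        libs = [self._library("egg", {"C0": 5}), self._library("pupa", {"C0": 0, "X": 1})]
        table = diversity_table([cluster], libs, STAGES).table
        assert table.loc["egg", "oxidation_reduction"] == 1
        assert table.loc["pupa", "oxidation_reduction"] == 0
        assert table.loc[ALL_STAGES, "oxidation_reduction"] == 1

    def test_stage_membership_falls_back_to_origin_labels(self):
        cluster = make_cluster(1000, [600], stage="egg")
        table = diversity_table([cluster], None, STAGES).table
        assert table.loc["egg", "oxidation_reduction"] == 1
        assert table.loc["pupa", "oxidation_reduction"] == 0

    def test_unknown_stage_label_rejected(self):
        cluster = make_cluster(1000, [600])
        libs = [self._library("larva_x", {"C0": 5})]
        with pytest.raises(ValidationError):
            diversity_table([cluster], libs, STAGES)


@pytest.mark.parametrize("short_prob, frag_rate", [(1.0, 2.5), (0.0, 1.0)])
def test_ground_truth_recovery(short_prob, frag_rate):
    """With all-short fragments (or one long contig per gene) the inferred
    per-category counts equal the generating gene counts exactly."""
    p = SimulationParams(
        short_fragment_prob=short_prob,
        fragmentation_rate=frag_rate,
        seed=13,
    )
    ds = simulate_dataset(p)
    annotated = annotate(ds.contigs, ds.hits)
    clean, _ = flag_contaminants(annotated)
    clusters = cluster_by_subject([a for a in clean if a.best_hit])
    table = diversity_table(clusters, ds.libraries, p.stages).table
    truth = ds.true_category_counts()
    for category, n in truth.items():
        assert int(table.loc[ALL_STAGES, category]) == n


class TestFamilyTable:
    def test_subfamily_subrow(self):
        cluster = make_cluster(
            1000, [600, 700, 800],
            family="cytochrome P450", subfamily="CYP6",
        )
        libs = [StageLibrary(s, {"C0": 1, "C1": 1, "C2": 1}) for s in STAGES]
        table = family_table([cluster], libs, STAGES)
        assert table.loc[("cytochrome P450", ""), ALL_STAGES] == 3
        assert table.loc[("cytochrome P450", "CYP6"), ALL_STAGES] == 3

    def test_subrow_totals_never_exceed_family_row(self):
        rng = np.random.default_rng(7)
        clusters = []
        for i in range(30):
            sub = rng.choice(["", "CYP4", "CYP6"])
            c = make_cluster(
                1000, rng.integers(200, 1000, size=int(rng.integers(1, 4))).tolist(),
                family="cytochrome P450", subfamily=str(sub),
            )
            c.subject_accession = f"G{i}"
            for m in c.members:
                object.__setattr__(m.best_hit, "subject_accession", f"G{i}")
            clusters.append(c)
        libs = [StageLibrary(s, {m.contig.contig_id: 1 for c in clusters for m in c.members})
                for s in STAGES]
        table = family_table(clusters, libs, STAGES)
        fam_row = table.loc[("cytochrome P450", "")]
        for sub in ("CYP4", "CYP6"):
            if ("cytochrome P450", sub) in table.index:
                assert (table.loc[("cytochrome P450", sub)] <= fam_row).all()

    def test_species_merge_zero_fills_missing_families(self, tmp_path):
        cluster = make_cluster(1000, [600], family="nitrilase", subfamily="",
                               category="hydrolysis")
        other = tmp_path / "species.tsv"
        other.write_text("family\tsubfamily\tcount\nglycosidase\t\t7\n")
        table = species_comparison_table([cluster], {"other bee": other})
        assert table.loc[("nitrilase", ""), "this study"] == 1
        assert table.loc[("nitrilase", ""), "other bee"] == 0
        assert table.loc[("glycosidase", ""), "other bee"] == 7


def test_cluster_audit_records_rule_branch():
    clusters = [
        make_cluster(1000, [300, 400]),
        make_cluster(1000, [600, 700]),
        make_cluster(1000, [300, 600]),
    ]
    audit = cluster_audit(clusters)
    assert list(audit["rule_branch"]) == ["all_short", "all_long", "mixed"]
    assert list(audit["mixed_flag"]) == [0, 0, 1]
    assert list(audit["inferred_gene_count"]) == [1, 2, 2]


def test_detox_clusters_excludes_unclassified():
    keep = make_cluster(1000, [600])
    drop = make_cluster(1000, [600], category="none", family="")
    drop.category = "none"
    assert detox_clusters([keep, drop]) == [keep]
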