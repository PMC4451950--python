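"""Annotation cascade: category assignment order, partition invariants,
summaries, length histograms and base composition."""

import dataclasses

import numpy as np
import pytest

from somapir.annotate import (
    CATEGORIES,
    AnnotatedRead,
    AnnotationBreakdown,
    base_composition,
    classify_reads,
    size_histogram,
    summarize,
)
from somapir.simulate import ScenarioConfig, SmallRNALibrary, simulate_library


def _lib(reads):
    return SmallRNALibrary("t", [(f"r{i}", s) for i, s in enumerate(reads)])


class TestCascade:
    def test_genome_mapper_sizes(self, bundle):
        g = bundle.genome
        reads = {
            "piRNA": g[500:525],  # 25 nt mapper
            "siRNA": g[600:621],  # 21 nt mapper
            "unclassified": g[700:722],  # 22 nt mapper
        }
        out = classify_reads(_lib(list(reads.values())), bundle)
        assert [r.category for r in out] == list(reads)

    def test_exhaustive_size_rule_over_all_lengths(self, bundle):
        # mapper reads of every library-legal length, none ncRNA/miRNA
        reads = [bundle.genome[900 : 900 + L] for L in range(18, 30)]
        out = classify_reads(_lib(reads), bundle)
        expected = [
            "siRNA" if L == 21 else ("piRNA" if 23 <= L <= 29 else "unclassified")
            for L in range(18, 30)
        ]
        assert [r.category for r in out] == expected

    def test_ncrna_substring_takes_precedence(self, bundle):
        frag = next(iter(bundle.ncrna_set.values()))[10:35]
        out = classify_reads(_lib([frag]), bundle)
        assert out[0].category == "abundant_ncRNA"

    def test_mirna_identity_precedes_size_rule(self, bundle):
        # a mature miRNA that is also a perfect genome 21-mer must still be
        # called miRNA, not siRNA
        custom = dataclasses.replace(
            bundle,
            mirna_set={**bundle.mirna_set, "mir_genomic": bundle.genome[1200:1221]},
        )
        out = classify_reads(_lib([bundle.genome[1200:1221]]), custom)
        assert out[0].category == "miRNA"

    def test_nonmapper(self, bundle):
        read = "ACGT" * 6  # 24 nt, absent from the random genome
        assert read not in bundle.genome
        out = classify_reads(_lib([read]), bundle)
        assert out[0].category == "nonmapper"
        assert out[0].genome_hit_count == 0

    def test_empty_genome_rejected(self, bundle):
        broken = dataclasses.replace(bundle, genome="")
        with pytest.raises(ValueError):
            classify_reads(_lib(["ACGT" * 6]), broken)

    def test_cascade_idempotent(self, bundle, control_library):
        a = classify_reads(control_library, bundle)
        b = classify_reads(control_library, bundle)
        assert [r.category for r in a] == [r.category for r in b]

    def test_every_read_gets_exactly_one_category(self, annotated_control):
        assert all(r.category in CATEGORIES for r in annotated_control)

    def test_counts_match_truth_on_zero_mismatch_library(
        self, bundle, control_library, annotated_control, breakdown_control
    ):
        truth = control_library.truth["source_class"]
        expected = {
            "abundant_ncRNA": (truth == "ncRNA_fragment").sum(),
            "miRNA": (truth == "miRNA").sum(),
            "piRNA": truth.isin(
                [
                    "germline_cluster_piRNA",
                    "somatic_cluster_piRNA",
                    "soma_TE_piRNA",
                    "germline_TE_piRNA",
                    "utr_piRNA",
                ]
            ).sum(),
        }
        counts = breakdown_control.category_counts
        for cat, n in expected.items():
            assert counts[cat] == n
        assert counts["nonmapper"] == 0 and counts["siRNA"] == 0


class TestSummarize:
    def test_partition_sums_to_library_size(self, breakdown_control, control_library):
        assert breakdown_control.total_reads == len(control_library)
        assert (
            sum(breakdown_control.category_counts.values())
            == breakdown_control.total_reads
        )

    def test_all_pirna_breakdown(self, bundle):
        reads = [bundle.genome[100 + 30 * i : 125 + 30 * i] for i in range(10)]
        annotated = classify_reads(_lib(reads), bundle)
        bd = summarize(annotated, bundle, "t")
        assert bd.category_counts["piRNA"] == 10
        assert sum(bd.category_counts.values()) == 10

    def test_normalizer_only_library(self, bundle):
        cl = bundle.normalizer_cluster
        reads = [
            bundle.genome[cl.interval.start + 11 * i : cl.interval.start + 11 * i + 26]
            for i in range(12)
        ]
        annotated = classify_reads(_lib(reads), bundle)
        bd = summarize(annotated, bundle, "t")
        assert bd.cluster_unique_pirna[cl.id] == bd.category_counts["piRNA"] == 12

    def test_cluster_counts_bounded_by_pirna_count(self, breakdown_control):
        for n in breakdown_control.cluster_unique_pirna.values():
            assert n <= breakdown_control.category_counts["piRNA"]

    def test_inconsistent_breakdown_rejected(self):
        with pytest.raises(ValueError):
            AnnotationBreakdown("x", 5, {"piRNA": 4})


class TestHistogramAndComposition:
    def test_histogram_single_length(self, bundle):
        reads = [bundle.genome[50 + 40 * i : 75 + 40 * i] for i in range(5)]
        hist = size_histogram(classify_reads(_lib(reads), bundle))
        assert hist[25] == 5 and hist.sum() == 5

    def test_histogram_empty_selection_is_zero(self, annotated_control):
        hist = size_histogram(annotated_control, ["siRNA"])
        assert hist.sum() == 0

    def test_histogram_matches_truth_lengths(
        self, control_library, annotated_control
    ):
        hist = size_histogram(annotated_control)
        truth_counts = control_library.truth["length"].value_counts()
        for L in range(18, 30):
            assert hist[L] == truth_counts.get(L, 0)

    def test_all_t_reads(self):
        reads = [AnnotatedRead(f"r{i}", "T" * 25, "piRNA") for i in range(4)]
        mat = base_composition(reads, positions=8)
        assert (mat["T"] == 1.0).all()
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_rows_sum_to_one(self, annotated_control):
        mat = base_composition(annotated_control, ["piRNA"], positions=10)
        assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_u1_bias_visible_at_position_one(self, bundle):
        sc = ScenarioConfig(name="u1", u1_bias=0.8, seed=33)
        lib = simulate_library(bundle, sc, 15_000)
        annotated = classify_reads(lib, bundle)
        mat = base_composition(annotated, ["piRNA"], positions=5)
        n = sum(1 for r in annotated if r.category == "piRNA")
        sd = np.sqrt(0.8 * 0.2 / n)
        assert abs(mat.loc[1, "T"] - 0.8) <= 3 * sd

    def test_empty_selection_rejected(self, annotated_control):
        with pytest.raises(ValueError):
            base_composition(annotated_control, ["siRNA"])

    def test_positions_beyond_shortest_read_rejected(self, annotated_control):
        with pytest.raises(ValueError):
            base_composition(annotated_control, positions=30)
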