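"""Normalization, counting, profiling, comparison and enrichment."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from somapir.annotate import AnnotatedRead, classify_reads, summarize
from somapir.quantify import (
    CountTable,
    compare_libraries,
    fold_changes,
    interval_counts,
    normalization_factor,
    profile_feature,
    rip_enrichment,
    te_counts,
)
from somapir.simulate import ScenarioConfig, SmallRNALibrary, simulate_library


def _table(values: dict[str, float], library_id="lib", scale=1.0):
    df = pd.DataFrame(
        {
            "feature_class": "TE",
            "sense": list(values.values()),
            "antisense": 0,
        },
        index=pd.Index(values.keys(), name="feature_id"),
    )
    df["total_normalized"] = (df["sense"] + df["antisense"]) * scale
    return CountTable(library_id, scale, df)


class TestNormalization:
    @pytest.mark.parametrize("count,factor", [(500_000, 2.0), (1_000_000, 1.0)])
    def test_factor_values(self, count, factor):
        from somapir.annotate import AnnotationBreakdown

        bd = AnnotationBreakdown("x", count, {"piRNA": count}, {"norm": count})
        assert normalization_factor(bd, "norm") == factor

    def test_zero_normalizer_is_an_error(self, breakdown_control):
        bd = dataclasses.replace(
            breakdown_control, cluster_unique_pirna={"norm": 0}
        )
        with pytest.raises(ValueError, match="cannot normalize"):
            normalization_factor(bd, "norm")

    def test_scaled_normalizer_mass_is_one_million(
        self, bundle, breakdown_control
    ):
        norm = bundle.normalizer_cluster.id
        factor = normalization_factor(breakdown_control, norm)
        mass = breakdown_control.cluster_unique_pirna[norm] * factor
        assert mass == pytest.approx(1_000_000, rel=1e-12)


class TestTECounts:
    def test_single_read_single_family(self, bundle):
        te = bundle.te_panel[0]
        read = AnnotatedRead("r0", te.sequence[50:75], "piRNA")
        table = te_counts([read], bundle.panel_sequences, scale_factor=3.0)
        assert table.data.loc[te.id, "sense"] == 1
        assert table.data.loc[te.id, "total_normalized"] == 3.0
        others = table.data.drop(te.id)
        assert (others[["sense", "antisense"]] == 0).all().all()

    def test_read_hitting_two_families_counts_in_both(self, bundle):
        a, b = bundle.te_panel[0], bundle.te_panel[1]
        panel = {a.id: a.sequence, b.id: a.sequence[:300] + b.sequence[300:]}
        read = AnnotatedRead("r0", a.sequence[100:126], "piRNA")
        table = te_counts([read], panel)
        assert table.data.loc[a.id, "sense"] == 1
        assert table.data.loc[b.id, "sense"] == 1

    def test_once_per_family_despite_multiple_positions(self, bundle):
        te = bundle.te_panel[0]
        dup = te.sequence + te.sequence  # every read matches twice
        read = AnnotatedRead("r0", te.sequence[10:36], "piRNA")
        table = te_counts([read], {"dup": dup})
        assert table.data.loc["dup", "sense"] == 1

    def test_counts_match_truth_labels(self, bundle):
        # TE-only scenario: without cluster-class reads (which legitimately
        # overlap the embedded fragments) family counts equal truth exactly
        sc = ScenarioConfig(
            name="teonly",
            source_weights={
                "soma_TE_piRNA": 0.4,
                "germline_TE_piRNA": 0.3,
                "utr_piRNA": 0.2,
                "miRNA": 0.1,
            },
            seed=61,
        )
        lib = simulate_library(bundle, sc, 8_000)
        annotated = classify_reads(lib, bundle)
        table = te_counts(
            annotated,
            bundle.panel_sequences,
            {t.id: t.te_class for t in bundle.te_panel},
            scale_factor=2.0,
        )
        truth = lib.truth
        te_truth = truth[truth["source_class"].isin(["soma_TE_piRNA", "germline_TE_piRNA"])]
        for te_id, expected in te_truth.groupby("feature_id").size().items():
            assert table.data.loc[te_id, "antisense"] == expected
            assert table.data.loc[te_id, "total_normalized"] == expected * 2.0
        # no sense-strand TE piRNAs exist in these libraries
        assert (table.data["sense"] == 0).all()

    def test_empty_panel_rejected(self, annotated_control):
        with pytest.raises(ValueError):
            te_counts(annotated_control, {})


class TestProfiles:
    def test_single_read_profile(self, bundle):
        te = bundle.te_panel[0]
        read = AnnotatedRead("r0", te.sequence[100:125], "piRNA")
        track = profile_feature([read], te.id, bundle, scale_factor=2.5)
        assert track.sense[100] == 2.5
        assert track.sense.sum() == 2.5 and track.antisense.sum() == 0

    def test_mass_conservation_unique_policy(self, bundle, annotated_control):
        cl = bundle.normalizer_cluster
        track = profile_feature(annotated_control, cl.id, bundle)
        contributing = sum(
            1
            for r in annotated_control
            if r.category == "piRNA"
            and r.genome_unique
            and cl.interval.contains(r.genome_hits[0].start, r.genome_hits[0].end)
        )
        assert track.policy == "genome_unique_only"
        assert track.total_mass == contributing

    def test_somatic_cluster_te_mass_is_antisense(self, bundle, annotated_control):
        # soma TE fragments sit antisense in the somatic cluster, so on the
        # consensus axis their piRNA mass must be overwhelmingly antisense
        soma_te = [t for t in bundle.te_panel if t.te_class == "soma_dominant"][0]
        track = profile_feature(annotated_control, soma_te.id, bundle)
        assert track.antisense.sum() > 50
        assert track.antisense.sum() > 10 * track.sense.sum()

    def test_unknown_feature_rejected(self, bundle, annotated_control):
        with pytest.raises(KeyError):
            profile_feature(annotated_control, "no_such_feature", bundle)

    def test_interval_profile_follows_feature_orientation(self, bundle):
        utr = [u for u in bundle.utr_sources if u.strand == "-"][0]
        # a read sense to a minus-strand gene: minus-strand alignment whose
        # 5' end sits at interval.end - 1 - local
        s, e = utr.interval.start, utr.interval.end
        read_seq = bundle.genome[e - 26 : e]
        from somapir.align import revcomp

        annotated = classify_reads(
            SmallRNALibrary("t", [("r0", revcomp(read_seq))]), bundle
        )
        track = profile_feature(annotated, utr.gene_id, bundle)
        assert track.sense[0] == 1.0  # 5' end at the gene's own 5' extremity


class TestComparisons:
    def test_identical_tables_r_one(self):
        t = _table({"a": 1, "b": 2, "c": 3})
        res = compare_libraries(t, t)
        assert res.pearson_r == pytest.approx(1.0)

    def test_antilinear_r_minus_one(self):
        a = _table({"x": 1, "y": 2, "z": 3})
        b = _table({"x": 3, "y": 2, "z": 1})
        assert compare_libraries(a, b).pearson_r == pytest.approx(-1.0)

    def test_r_matches_textbook_formula(self):
        xs, ys = (1.0, 2.0, 4.0), (2.0, 3.0, 9.0)
        a = _table(dict(zip("abc", xs)))
        b = _table(dict(zip("abc", ys)))
        mx, my = sum(xs) / 3, sum(ys) / 3
        cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        vx = sum((x - mx) ** 2 for x in xs)
        vy = sum((y - my) ** 2 for y in ys)
        expected = cov / np.sqrt(vx * vy)
        assert compare_libraries(a, b).pearson_r == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_flagged(self):
        a = _table({"x": 1, "y": 1})
        b = _table({"x": 1, "y": 2})
        res = compare_libraries(a, b)
        assert not res.r_defined and np.isnan(res.pearson_r)

    def test_mismatched_panels_rejected(self):
        with pytest.raises(ValueError):
            compare_libraries(_table({"x": 1, "y": 2}), _table({"x": 1, "z": 2}))

    def test_depth_invariance(self, bundle, annotated_control):
        """Duplicating every read leaves normalized counts and r unchanged."""
        doubled = annotated_control + [
            AnnotatedRead(r.read_id + "_d", r.sequence, r.category, r.genome_hits)
            for r in annotated_control
        ]
        norm = bundle.normalizer_cluster.id
        bd1 = summarize(annotated_control, bundle, "a")
        bd2 = summarize(doubled, bundle, "b")
        f1 = normalization_factor(bd1, norm)
        f2 = normalization_factor(bd2, norm)
        t1 = interval_counts(annotated_control, bundle, f1, "a")
        t2 = interval_counts(doubled, bundle, f2, "b")
        assert np.allclose(
            t1.data["total_normalized"], t2.data["total_normalized"], rtol=1e-12
        )
        fc = fold_changes(t2, t1, pseudocount=0.0)
        assert np.allclose(fc["fold_change"].dropna(), 1.0)


class TestFoldChanges:
    def test_equal_tables_give_unit_ratio(self):
        t = _table({"a": 5, "b": 9})
        assert (fold_changes(t, t)["fold_change"] == 1.0).all()

    def test_quarter_ratio_without_pseudocount(self):
        cond = _table({"a": 25.0})
        ctrl = _table({"a": 100.0})
        fc = fold_changes(cond, ctrl, pseudocount=0.0)
        assert fc.loc["a", "fold_change"] == 0.25

    def test_pseudocount_guards_zero_control(self):
        fc = fold_changes(_table({"a": 3.0}), _table({"a": 0.0}), pseudocount=1.0)
        assert fc.loc["a", "fold_change"] == 4.0


class TestRipEnrichment:
    def _annotated(self, bundle, reads):
        return classify_reads(
            SmallRNALibrary("t", [(f"r{i}", s) for i, s in enumerate(reads)]), bundle
        )

    def test_identical_libraries_unit_enrichment(self, bundle, annotated_control):
        enr = rip_enrichment(annotated_control, annotated_control, bundle)
        assert np.allclose(enr["enrichment"], 1.0)

    def test_bound_feature_ranks_first(self, bundle):
        sc_input = ScenarioConfig(name="inp", seed=51)
        sc_ip = ScenarioConfig(
            name="ip", depletion={"somatic_cluster_piRNA": 6.0}, seed=52
        )
        inp = classify_reads(simulate_library(bundle, sc_input, 8_000), bundle)
        ip = classify_reads(simulate_library(bundle, sc_ip, 8_000), bundle)
        enr = rip_enrichment(ip, inp, bundle)
        soma = [c.id for c in bundle.clusters if c.role == "somatic"][0]
        assert enr["enrichment"].idxmax() == soma

    def test_no_unique_reads_is_an_error(self, bundle):
        nonmapper = self._annotated(bundle, ["ACGT" * 6])
        with pytest.raises(ValueError, match="genome-unique"):
            rip_enrichment(nonmapper, nonmapper, bundle)
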