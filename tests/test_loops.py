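import numpy as np
import pytest

from regulome.core_io import (ContactMatrix, GenomicInterval, Loop,
                              SampleDesign, ValidationError)
from regulome.loops import (anchor_enrichment, annotate_loops, apa,
                            assign_subtype_loops, category_fractions,
                            tumor_support)
from regulome.svmap import decay_curve


def make_loop(b1, b2, probs=None, chrom="chr1", res=10_000):
    return Loop(chrom, b1, chrom, b2, res, probs=dict(probs or {}))


DESIGN = [SampleDesign("lum_1", "luminal"), SampleDesign("lum_2", "luminal"),
          SampleDesign("bas_1", "basal"), SampleDesign("bas_2", "basal")]


class TestSubtypeAssignment:
    def test_clear_separation_is_group_specific(self):
        lp = make_loop(10, 50, {"lum_1": 0.9, "lum_2": 0.9,
                                "bas_1": 0.1, "bas_2": 0.2})
        assign_subtype_loops([lp], DESIGN)
        assert lp.subtype_call == "luminal"

    def test_high_everywhere_is_shared(self):
        lp = make_loop(10, 50, {s.sample_id: 0.95 for s in DESIGN})
        assign_subtype_loops([lp], DESIGN)
        assert lp.subtype_call == "shared"

    def test_intermediate_probabilities_unassigned(self):
        lp = make_loop(10, 50, {"lum_1": 0.9, "lum_2": 0.9,
                                "bas_1": 0.7, "bas_2": 0.1})
        assign_subtype_loops([lp], DESIGN)
        assert lp.subtype_call == "unassigned"

    def test_group_sets_disjoint_for_any_valid_thresholds(self):
        rng = np.random.default_rng(0)
        loops = [make_loop(i, i + 30,
                           {s.sample_id: float(p)
                            for s, p in zip(DESIGN, rng.uniform(0, 1, 4))})
                 for i in range(200)]
        for p_high, p_low in ((0.8, 0.5), (0.6, 0.59), (0.9, 0.1)):
            assign_subtype_loops(loops, DESIGN, p_high, p_low)
            lum = {lp.key() for lp in loops if lp.subtype_call == "luminal"}
            bas = {lp.key() for lp in loops if lp.subtype_call == "basal"}
            assert not (lum & bas)

    def test_inverted_thresholds_error(self):
        with pytest.raises(ValidationError):
            assign_subtype_loops([], DESIGN, p_high=0.5, p_low=0.8)

    def test_missing_probability_column_errors(self):
        lp = make_loop(10, 50, {"lum_1": 0.9})
        with pytest.raises(ValidationError, match="lacks probability"):
            assign_subtype_loops([lp], DESIGN)


class TestAnnotation:
    PROMOTERS = [GenomicInterval("chr1", 100_000, 105_000)]
    ENHANCERS = [GenomicInterval("chr1", 500_000, 500_800),
                 GenomicInterval("chr1", 100_000, 100_300)]  # also under P

    def test_promoter_enhancer_pair_is_EP(self):
        lp = make_loop(10, 50)   # anchors 100-110kb and 500-510kb
        annotate_loops([lp], self.PROMOTERS, self.ENHANCERS)
        assert lp.category == "E-P"

    def test_promoter_beats_enhancer_on_dual_overlap(self):
        lp = make_loop(10, 30)
        annotate_loops([lp], self.PROMOTERS, self.ENHANCERS)
        # anchor1 overlaps both a promoter and an enhancer -> P
        assert lp.category == "P-N"

    def test_bare_anchors_are_none(self):
        lp = make_loop(700, 900)
        annotate_loops([lp], self.PROMOTERS, self.ENHANCERS)
        assert lp.category == "None"

    def test_fractions_match_quadratic_oracle_and_sum_to_one(self):
        rng = np.random.default_rng(1)
        promoters = [GenomicInterval("chr1", int(s), int(s) + 2_000)
                     for s in rng.integers(0, 5_000_000, 40)]
        enhancers = [GenomicInterval("chr1", int(s), int(s) + 600)
                     for s in rng.integers(0, 5_000_000, 80)]
        loops = [make_loop(int(b), int(b) + int(d))
                 for b, d in zip(rng.integers(0, 400, 200),
                                 rng.integers(5, 80, 200))]
        annotate_loops(loops, promoters, enhancers)

        def olaps(anchor, ivs):
            return any(anchor.chrom == iv.chrom and anchor.start < iv.end
                       and iv.start < anchor.end for iv in ivs)

        for lp in loops:
            labels = []
            for anchor in (lp.anchor1, lp.anchor2):
                if olaps(anchor, promoters):
                    labels.append("P")
                elif olaps(anchor, enhancers):
                    labels.append("E")
                else:
                    labels.append("N")
            expect = {("E", "P"): "E-P", ("E", "E"): "E-E", ("P", "P"): "P-P",
                      ("E", "N"): "E-N", ("N", "P"): "P-N",
                      ("N", "N"): "None"}[tuple(sorted(labels))]
            assert lp.category == expect
        assert sum(category_fractions(loops).values()) == pytest.approx(1.0)


class TestTumorSupport:
    def _called(self, loops, call):
        for lp in loops:
            lp.subtype_call = call
        return loops

    def test_identical_tumor_set_gives_full_support(self):
        loops = self._called([make_loop(10, 50), make_loop(20, 90)], "luminal")
        out = tumor_support(loops, [[make_loop(10, 50), make_loop(20, 90)]])
        assert out == {"luminal": 1.0}

    def test_empty_tumor_sets_give_zero(self):
        loops = self._called([make_loop(10, 50)], "basal")
        assert tumor_support(loops, [[]]) == {"basal": 0.0}

    def test_one_bin_jitter_needs_slack_one(self):
        loops = self._called([make_loop(10, 50)], "luminal")
        jittered = [[make_loop(11, 49)]]
        assert tumor_support(loops, jittered, slack_bins=1) == {"luminal": 1.0}
        assert tumor_support(loops, jittered, slack_bins=0) == {"luminal": 0.0}

    def test_resolution_mismatch_errors(self):
        loops = self._called([make_loop(10, 50)], "luminal")
        with pytest.raises(ValidationError, match="resolution"):
            tumor_support(loops, [[make_loop(10, 50, res=5_000)]])


def decay_values(n, scale=100.0, alpha=1.0):
    d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    return scale * (1.0 + d) ** (-alpha)


class TestApa:
    def test_flat_field_gives_unit_aggregate_and_score(self):
        cm = ContactMatrix("chr1", "chr1", 10_000, np.full((200, 200), 5.0))
        res = apa(cm, [make_loop(60, 120), make_loop(40, 150)], w=10)
        np.testing.assert_allclose(res.aggregate, 1.0, atol=1e-12)
        assert res.score == pytest.approx(1.0)
        assert res.n_used == 2 and res.n_skipped == 0

    def test_single_noiseless_dot_scores_planted_enrichment(self):
        n, enrich = 300, 3.0
        values = decay_values(n)
        b1, b2 = 100, 160
        values[b1, b2] *= enrich
        values[b2, b1] *= enrich
        cm = ContactMatrix("chr1", "chr1", 10_000, values)
        truth_expected = 100.0 * (1.0 + np.arange(n)) ** -1.0
        res = apa(cm, [make_loop(b1, b2)], w=10, expected=truth_expected)
        assert res.score == pytest.approx(enrich, abs=1e-6)

    def test_invariant_under_global_matrix_scaling(self):
        rng = np.random.default_rng(2)
        raw = rng.poisson(decay_values(250))
        vals = ((raw + raw.T) / 2).astype(float)
        loops = [make_loop(50, 120), make_loop(80, 200), make_loop(130, 190)]
        a = apa(ContactMatrix("chr1", "chr1", 10_000, vals), loops)
        b = apa(ContactMatrix("chr1", "chr1", 10_000, vals * 7.5), loops)
        np.testing.assert_allclose(a.aggregate, b.aggregate, rtol=1e-12)
        assert a.score == pytest.approx(b.score)

    def test_near_diagonal_and_edge_loops_skipped(self):
        cm = ContactMatrix("chr1", "chr1", 10_000, np.full((100, 100), 2.0))
        res = apa(cm, [make_loop(40, 50),     # too close to diagonal
                       make_loop(5, 60),      # touches left edge
                       make_loop(30, 70)], w=10)
        assert res.n_used == 1 and res.n_skipped == 2
        with pytest.raises(ValidationError, match="skipped"):
            apa(cm, [make_loop(40, 50)], w=10)

    def test_matches_bruteforce_observed_over_expected(self):
        rng = np.random.default_rng(3)
        raw = rng.poisson(decay_values(120, scale=50.0))
        vals = ((raw + raw.T) / 2).astype(float)
        cm = ContactMatrix("chr1", "chr1", 10_000, vals)
        loops = [make_loop(20, 60), make_loop(45, 100), make_loop(30, 80)]
        w = 5
        res = apa(cm, loops, w=w)
        # independent brute force with explicit python loops
        n = 120
        exp = [np.mean([vals[i, i + d] for i in range(n - d)])
               for d in range(n)]
        agg = np.zeros((2 * w + 1, 2 * w + 1))
        for lp in loops:
            for di in range(-w, w + 1):
                for dj in range(-w, w + 1):
                    i, j = lp.bin_a + di, lp.bin_b + dj
                    agg[di + w, dj + w] += vals[i, j] / exp[abs(j - i)]
        agg /= len(loops)
        np.testing.assert_allclose(res.aggregate, agg, atol=1e-10)
        corner = agg[2 * w - 2:, :3]
        assert res.score == pytest.approx(agg[w, w] / corner.mean(), abs=1e-10)


class TestAnchorEnrichment:
    CHROM_SIZES = {"chr1": 5_000_000}

    def test_sites_only_inside_anchors_is_extreme(self):
        loops = [make_loop(10, 50), make_loop(100, 200)]
        sites = [GenomicInterval("chr1", 100_000 + k * 100, 100_000 + k * 100 + 10)
                 for k in range(20)]          # all inside bin 10
        fold, p = anchor_enrichment(loops, sites, self.CHROM_SIZES,
                                    n_shuffles=200, seed=0)
        assert fold > 3.0
        assert p == pytest.approx(1 / 201)

    def test_missing_chromosome_errors(self):
        loops = [make_loop(10, 50)]
        sites = [GenomicInterval("chrX", 0, 10)]
        with pytest.raises(ValidationError, match="chrX"):
            anchor_enrichment(loops, sites, self.CHROM_SIZES)

    def test_uniform_sites_are_not_enriched(self):
        rng = np.random.default_rng(4)
        loops = [make_loop(int(b), int(b) + 40)
                 for b in rng.integers(20, 400, 20)]
        sites = [GenomicInterval("chr1", int(s), int(s) + 10)
                 for s in rng.integers(0, 4_999_000, 500)]
        fold, p = anchor_enrichment(loops, sites, self.CHROM_SIZES,
                                    n_shuffles=300, seed=1)
        assert 0.7 < fold < 1.3
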