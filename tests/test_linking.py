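import numpy as np
import pytest
from scipy import stats

from regulome.core_io import GeneAnnotation, GenomicInterval, ValidationError
from regulome.linking import (correlate_links, empirical_null, score_links,
                              select_variable_enhancers)
from conftest import activity_from_array


def toy_genes(rng, n, chroms=("chr1", "chr2"), span=2_000_000):
    return [GeneAnnotation(f"g{i}", str(rng.choice(chroms)),
                           int(rng.integers(0, span)),
                           str(rng.choice(["+", "-"])))
            for i in range(n)]


def toy_coords(rng, ids, chroms=("chr1", "chr2"), span=2_000_000):
    out = {}
    for eid in ids:
        start = int(rng.integers(0, span))
        out[eid] = GenomicInterval(str(rng.choice(chroms)), start, start + 500,
                                   ".", eid)
    return out


class TestVariableSelection:
    def test_constant_enhancer_ranks_last(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(size=(10, 5))
        arr[3] = 2.0                       # zero variance
        act = activity_from_array(arr, prefix="e")
        coords = toy_coords(rng, act.feature_ids)
        order = select_variable_enhancers(act, coords, 10)
        assert order[-1] == "e3"

    def test_full_selection_is_identity_set(self):
        rng = np.random.default_rng(1)
        act = activity_from_array(rng.normal(size=(20, 4)), prefix="e")
        coords = toy_coords(rng, act.feature_ids)
        assert set(select_variable_enhancers(act, coords, 20)) == \
            set(act.feature_ids)

    def test_order_matches_bruteforce_variance_sort(self):
        rng = np.random.default_rng(2)
        act = activity_from_array(rng.normal(size=(100, 6)), prefix="e")
        coords = toy_coords(rng, act.feature_ids)
        order = select_variable_enhancers(act, coords, 100)
        var = {eid: np.var(act.data.loc[eid], ddof=1)
               for eid in act.feature_ids}
        brute = sorted(act.feature_ids,
                       key=lambda e: (-var[e], coords[e].chrom, coords[e].start))
        assert order == brute

    def test_overlong_request_errors(self):
        rng = np.random.default_rng(3)
        act = activity_from_array(rng.normal(size=(5, 4)), prefix="e")
        with pytest.raises(ValidationError):
            select_variable_enhancers(act, toy_coords(rng, act.feature_ids), 6)


class TestCorrelate:
    def test_identical_and_antiproportional_vectors(self):
        genes = [GeneAnnotation("g0", "chr1", 100_000, "+")]
        expr = activity_from_array([[1.0, 2.0, 3.0, 4.0]], prefix="g")
        coords = {"e0": GenomicInterval("chr1", 90_000, 90_500, ".", "e0"),
                  "e1": GenomicInterval("chr1", 110_000, 110_500, ".", "e1")}
        act = activity_from_array([[1.0, 2.0, 3.0, 4.0],
                                   [4.0, 3.0, 2.0, 1.0]], prefix="e")
        links = correlate_links(act, coords, expr, genes, window=50_000)
        r = dict(zip(links["enhancer_id"], links["r"]))
        assert r["e0"] == pytest.approx(1.0)
        assert r["e1"] == pytest.approx(-1.0)

    def test_all_pairs_match_pointwise_pearson_oracle(self):
        rng = np.random.default_rng(4)
        genes = toy_genes(rng, 20)
        expr = activity_from_array(rng.normal(size=(20, 6)), prefix="g")
        act = activity_from_array(rng.normal(size=(50, 6)), prefix="e")
        coords = toy_coords(rng, act.feature_ids)
        links = correlate_links(act, coords, expr, genes, window=500_000)
        assert len(links) > 0
        gene_row = {g: i for i, g in enumerate(expr.feature_ids)}
        enh_row = {e: i for i, e in enumerate(act.feature_ids)}
        for row in links.itertuples():
            expect = stats.pearsonr(act.values[enh_row[row.enhancer_id]],
                                    expr.values[gene_row[row.gene_id]])[0]
            assert row.r == pytest.approx(expect, abs=1e-12)
            gene = next(g for g in genes if g.gene_id == row.gene_id)
            assert gene.chrom == coords[row.enhancer_id].chrom
            assert row.distance <= 500_000

    def test_zero_variance_vector_flagged_degenerate(self):
        genes = [GeneAnnotation("g0", "chr1", 100_000, "+")]
        expr = activity_from_array([[1.0, 2.0, 3.0, 4.0]], prefix="g")
        coords = {"e0": GenomicInterval("chr1", 99_000, 99_500, ".", "e0")}
        act = activity_from_array([[5.0, 5.0, 5.0, 5.0]], prefix="e")
        links = correlate_links(act, coords, expr, genes, window=50_000)
        assert links["degenerate"].iloc[0] and links["r"].iloc[0] == 0.0

    def test_fewer_than_three_shared_samples_errors(self):
        genes = [GeneAnnotation("g0", "chr1", 0, "+")]
        expr = activity_from_array([[1.0, 2.0]], prefix="g",
                                   samples=["s0", "s1"])
        act = activity_from_array([[1.0, 2.0]], prefix="e",
                                  samples=["s0", "s9"])
        with pytest.raises(ValidationError, match="shared"):
            correlate_links(act, {"e0": GenomicInterval("chr1", 0, 500, ".",
                                                        "e0")},
                            expr, genes, window=1000)


class TestNull:
    def test_same_seed_reproduces_null_sample(self):
        rng = np.random.default_rng(5)
        genes = toy_genes(rng, 30)
        expr = activity_from_array(rng.normal(size=(30, 6)), prefix="g")
        act = activity_from_array(rng.normal(size=(40, 6)), prefix="e")
        coords = toy_coords(rng, act.feature_ids)
        a = empirical_null(act, coords, expr, genes, 500, seed=9)
        b = empirical_null(act, coords, expr, genes, 500, seed=9)
        np.testing.assert_array_equal(a, b)
        assert abs(a.mean()) < 0.1

    def test_zero_draws_or_single_chromosome_error(self):
        rng = np.random.default_rng(6)
        genes = toy_genes(rng, 10, chroms=("chr1",))
        expr = activity_from_array(rng.normal(size=(10, 6)), prefix="g")
        act = activity_from_array(rng.normal(size=(10, 6)), prefix="e")
        coords = toy_coords(rng, act.feature_ids, chroms=("chr1",))
        with pytest.raises(ValidationError):
            empirical_null(act, coords, expr, genes, 0, seed=0)
        with pytest.raises(ValidationError, match="single chromosome"):
            empirical_null(act, coords, expr, genes, 100, seed=0)


class TestScore:
    def _links(self, rs):
        import pandas as pd
        return pd.DataFrame({"enhancer_id": [f"e{i}" for i in range(len(rs))],
                             "gene_id": "g", "distance": 0, "r": rs,
                             "degenerate": False})

    def test_extreme_r_attains_smallest_possible_p(self):
        null = np.linspace(-0.9, 0.9, 199)
        out = score_links(self._links([1.0]), null)
        assert out["p_emp"].iloc[0] == pytest.approx(1 / 200)
        assert out["passes"].iloc[0]

    def test_r_below_entire_null_has_p_near_one(self):
        null = np.linspace(-0.5, 0.9, 200)
        out = score_links(self._links([-0.99]), null)
        assert out["p_emp"].iloc[0] == pytest.approx(1.0)
        assert not out["passes"].iloc[0]

    def test_p_monotone_nonincreasing_in_r(self):
        rng = np.random.default_rng(7)
        null = rng.normal(0, 0.4, 1000)
        rs = np.linspace(-1, 1, 41)
        out = score_links(self._links(rs), null)
        assert (np.diff(out["p_emp"]) <= 1e-15).all()

    def test_negative_correlations_never_pass(self):
        null = np.linspace(-0.99, 0.99, 500)
        out = score_links(self._links([-0.95, -0.6]), null)
        assert not out["passes"].any()
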