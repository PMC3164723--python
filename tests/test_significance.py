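import numpy as np
import pytest

from gmi import (
    PermutationNull,
    SyntheticSpec,
    attach_significance,
    average_gmi,
    build_null,
    generate,
    p_values,
    q_values,
    select_markers,
)


def null_from_array(arr, B=None):
    arr = np.asarray(arr, dtype=float)
    return PermutationNull(values=arr, B=arr.shape[0], R=1, seed=0)


def brute_force_p(observed, null_values):
    """Double loop over permutations and genes (pooled tail count)."""
    B, G = null_values.shape[:2]
    out = np.zeros_like(observed)
    for g in range(observed.shape[0]):
        for n in range(observed.shape[1]):
            count = 0
            for b in range(B):
                for g2 in range(G):
                    count += null_values[b, g2, n] >= observed[g, n]
            out[g, n] = count / (B * G)
    return out


class TestPValues:
    def test_matches_brute_force_double_loop(self, rng):
        B, G, L = 7, 9, 2
        null = null_from_array(rng.uniform(size=(B, G, L)))
        observed = rng.uniform(size=(G, L))
        assert np.array_equal(p_values(observed, null), brute_force_p(observed, null.values))

    def test_untouched_maximum_gets_zero(self):
        null = null_from_array(np.full((3, 4, 1), 0.5))
        p = p_values(np.array([[0.9], [0.5], [0.1]]), null)
        assert p[0, 0] == 0.0  # exceeded by no null value
        assert p[1, 0] == 1.0  # >= is the tail convention
        assert p[2, 0] == 1.0

    def test_smallest_nonzero_p_is_one_over_BG(self, rng):
        B, G = 5, 8
        null = null_from_array(rng.uniform(size=(B, G, 1)))
        observed = np.sort(null.values[:, :, 0].ravel())[-1][None, None]
        p = p_values(observed, null)
        assert p[0, 0] == pytest.approx(1 / (B * G))

    def test_nonincreasing_in_observed_statistic(self, rng):
        null = null_from_array(rng.uniform(size=(10, 20, 1)))
        observed = np.sort(rng.uniform(size=(20, 1)), axis=0)
        p = p_values(observed, null)
        assert (np.diff(p[:, 0]) <= 0).all()


class TestQValues:
    def test_single_gene_q_equals_p(self, rng):
        null = null_from_array(rng.uniform(size=(6, 1, 1)))
        observed = rng.uniform(size=(1, 1))
        assert q_values(observed, null)[0, 0] == pytest.approx(
            p_values(observed, null)[0, 0]
        )

    def test_top_gene_with_zero_null_exceedances(self, rng):
        null = null_from_array(rng.uniform(0, 0.5, size=(4, 5, 1)))
        observed = rng.uniform(0, 0.4, size=(5, 1))
        observed[2, 0] = 0.99
        q = q_values(observed, null)
        assert q[2, 0] == 0.0

    def test_minimum_gene_clamps_to_one_on_toy_null(self):
        # brute-force evaluation of the empirical-FDR formula on a 5-gene
        # toy: for the overall minimum, every null and observed value is
        # an exceedance, so numerator/B = G and denominator = G -> q = 1
        null = null_from_array(np.array([[[0.5], [0.6], [0.7], [0.8], [0.9]]] * 3))
        observed = np.array([[0.05], [0.55], [0.65], [0.75], [0.95]])
        q = q_values(observed, null)
        assert q[0, 0] == 1.0

    def test_monotone_nonincreasing_in_observed(self, rng):
        null = null_from_array(rng.uniform(size=(8, 30, 1)))
        observed = rng.uniform(size=(30, 1))
        q = q_values(observed, null)[:, 0]
        order = np.argsort(-observed[:, 0])
        assert (np.diff(q[order]) >= 0).all()


class TestBuildNull:
    def test_shape_and_determinism(self, small_planted):
        data, _ = small_planted
        null = build_null(data, R=2, B=3, seed=5)
        assert null.values.shape == (3, data.n_genes, data.K - 1)
        again = build_null(data, R=2, B=3, seed=5)
        assert np.array_equal(null.values, again.values)
        assert not np.array_equal(
            null.values, build_null(data, R=2, B=3, seed=6).values
        )

    def test_constant_matrix_gives_all_zero_null(self):
        from gmi import LabeledExpressionMatrix

        data = LabeledExpressionMatrix(
            np.full((3, 12), 2.5),
            ("a", "b", "c"),
            tuple(f"s{i}" for i in range(12)),
            np.r_[[1] * 6, [2] * 6],
        )
        null = build_null(data, R=2, B=2, seed=0)
        assert np.array_equal(null.values, np.zeros_like(null.values))

    def test_pvalues_near_uniform_on_exchangeable_data(self):
        # labels carry no signal, so observed averaged GMI values are
        # draws from the same distribution as the null; KS sanity check
        from scipy.stats import kstest

        spec = SyntheticSpec(class_sizes=(10, 10), planted=(), n_noise_genes=60, seed=1)
        data, _ = generate(spec)
        observed = average_gmi(data, R=5, seed=2)
        null = build_null(data, R=5, B=40, seed=2)
        p = p_values(observed, null)[:, 0]
        assert kstest(p, "uniform").pvalue > 0.01

    def test_attach_fills_records(self, small_planted):
        data, _ = small_planted
        records = select_markers(data, R=5, N1=3, N2=3, seed=1)
        observed = average_gmi(data, R=5, seed=1)
        null = build_null(data, R=5, B=4, seed=1)
        filled = attach_significance(records, observed, null, data.gene_ids)
        for recs in filled.values():
            for r in recs:
                assert 0.0 <= r.p_value <= 1.0
                assert 0.0 <= r.q_value <= 1.0
        # the dominant planted marker should sit at p = 0
        assert filled[1][0].p_value == 0.0
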