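"""BH, q-value inversion, stratification, weight learning and cross-weighted IHW."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rvprior.simulate import SimConfig, simulate_loci, simulate_rvas_pvalues
from rvprior.weighting import (
    IndependentHypothesisWeighting,
    assign_strata,
    auto_n_bins,
    bh_adjust,
    bh_rejections,
    ihw,
    learn_stratum_weights,
    qvalues_to_pvalues,
    shuffled_covariate_control,
    stratified_pvalue_histogram,
)


def bh_threshold_scan_oracle(p, alpha):
    """Independent BH oracle: largest candidate threshold t in {p_i} with
    t <= alpha * #{p <= t} / m; reject everything at or below it."""
    p = np.asarray(p)
    m = p.size
    feasible = [t for t in np.unique(p) if t <= alpha * (p <= t).sum() / m]
    if not feasible:
        return np.zeros(m, dtype=bool)
    return p <= max(feasible)


class TestBH:
    def test_all_ones_no_rejections(self):
        _, rej = bh_rejections(np.ones(10), 0.3)
        assert rej.sum() == 0

    def test_single_hypothesis(self):
        adj, rej = bh_rejections([0.01], 0.05)
        assert rej[0]
        assert adj[0] == pytest.approx(0.01)

    def test_matches_threshold_scan_oracle(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 200))
            p = rng.random(m).round(int(rng.integers(1, 5)))
            alpha = float(rng.choice([0.05, 0.1, 0.2, 0.3]))
            _, rej = bh_rejections(p, alpha)
            np.testing.assert_array_equal(rej, bh_threshold_scan_oracle(p, alpha))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(500)
        adj, rej = bh_rejections(p, 0.1)
        sm_rej, sm_adj, _, _ = multipletests(p, alpha=0.1, method="fdr_bh")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
        np.testing.assert_array_equal(rej, sm_rej)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_rejections([0.1, 1.5], 0.05)
        with pytest.raises(ValueError):
            bh_rejections([0.1, np.nan], 0.05)


class TestQvaluesToPvalues:
    def test_closed_form_examples(self):
        np.testing.assert_allclose(qvalues_to_pvalues([0.05]), [0.05])
        np.testing.assert_allclose(qvalues_to_pvalues([0.03, 0.04]), [0.015, 0.04])

    def test_round_trip_through_bh(self, rng):
        q = np.sort(rng.random(500))
        p = qvalues_to_pvalues(q)
        np.testing.assert_allclose(bh_adjust(p), q, atol=1e-12, rtol=0)

    def test_unsorted_input_restored_to_original_order(self, rng):
        q = rng.random(100)
        p = qvalues_to_pvalues(q)
        # rank correspondence: smallest q gives smallest p
        assert np.argmin(p) == np.argmin(q)
        np.testing.assert_allclose(np.sort(bh_adjust(p)), np.maximum.accumulate(np.sort(q)),
                                   atol=1e-12)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            qvalues_to_pvalues([0.5, -0.1])


class TestAssignStrata:
    def test_single_bin(self):
        np.testing.assert_array_equal(assign_strata([3.0, 1.0, 2.0], 1), [0, 0, 0])

    def test_nine_values_three_bins(self):
        x = np.arange(1, 10, dtype=float)
        np.testing.assert_array_equal(assign_strata(x, 3), [0, 0, 0, 1, 1, 1, 2, 2, 2])

    @given(st.integers(1, 7), st.integers(0, 2**31 - 1))
    def test_sizes_within_one_even_with_heavy_ties(self, n_bins, seed):
        r = np.random.default_rng(seed)
        m = int(r.integers(n_bins, 200))
        x = r.integers(0, 3, size=m).astype(float)  # heavy ties
        sizes = np.bincount(assign_strata(x, n_bins), minlength=n_bins)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == m

    def test_strata_ordered_by_covariate(self, rng):
        x = rng.random(100)
        s = assign_strata(x, 4)
        means = [x[s == g].mean() for g in range(4)]
        assert np.all(np.diff(means) > 0)

    def test_too_many_bins_errors(self):
        with pytest.raises(ValueError):
            assign_strata([0.1, 0.2], 3)


def exhaustive_weight_oracle(p_by_stratum, alpha, grid=(0.0, 0.25, 0.5, 1.0, 2.0, 4.0)):
    """Independent exhaustive search: best grid rejection count achievable."""
    counts = np.array([len(s) for s in p_by_stratum], dtype=float)
    p = np.concatenate(p_by_stratum)
    strata = np.concatenate([np.full(len(s), g) for g, s in enumerate(p_by_stratum)])
    best = -1
    for masses in itertools.product(grid, repeat=len(p_by_stratum)):
        masses = np.array(masses, dtype=float)
        if masses @ counts == 0:
            continue
        w = masses * counts.sum() / (masses @ counts)
        with np.errstate(divide="ignore"):
            wp = np.where(w[strata] > 0, p / np.where(w[strata] > 0, w[strata], 1), np.inf)
        _, rej = bh_rejections(np.minimum(wp, 1.0), alpha)
        best = max(best, int(rej.sum()))
    return best


def achieved_rejections(p_by_stratum, w, alpha):
    p = np.concatenate(p_by_stratum)
    strata = np.concatenate([np.full(len(s), g) for g, s in enumerate(p_by_stratum)])
    with np.errstate(divide="ignore"):
        wp = np.where(w[strata] > 0, p / np.where(w[strata] > 0, w[strata], 1), np.inf)
    _, rej = bh_rejections(np.minimum(wp, 1.0), alpha)
    return int(rej.sum())


class TestLearnStratumWeights:
    def test_no_signal_ties_break_to_uniform(self, rng):
        strata = [np.linspace(0.5, 1.0, 50) for _ in range(3)]
        w = learn_stratum_weights(strata, alpha=0.1)
        np.testing.assert_allclose(w, np.ones(3))

    def test_signal_stratum_upweighted(self, rng):
        # stratum A: no small p-values at all; stratum B: 50 near-zero plus
        # uniform noise, so borderline hypotheses benefit from extra weight
        a = 0.5 + 0.5 * rng.random(500)
        b = np.concatenate([rng.random(450), rng.random(50) * 1e-4])
        w = learn_stratum_weights([a, b], alpha=0.1)
        assert w[1] > 1 > w[0]
        assert achieved_rejections([a, b], w, 0.1) >= achieved_rejections(
            [a, b], np.ones(2), 0.1
        )

    def test_budget_constraint(self, rng):
        strata = [rng.random(int(n)) for n in (30, 70, 50)]
        counts = np.array([30, 70, 50])
        w = learn_stratum_weights(strata, alpha=0.2)
        assert (w @ counts) / counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_grid_optimality_against_exhaustive_oracle(self, rng):
        for _ in range(5):
            strata = [
                np.concatenate([rng.random(40), rng.random(int(rng.integers(0, 10))) * 1e-4])
                for _ in range(3)
            ]
            w = learn_stratum_weights(strata, alpha=0.1)
            assert achieved_rejections(strata, w, 0.1) == exhaustive_weight_oracle(strata, 0.1)

    def test_coordinate_ascent_not_worse_than_uniform(self, rng):
        strata = [rng.random(60) * (0.1 if g >= 4 else 1.0) for g in range(6)]
        w = learn_stratum_weights(strata, alpha=0.1)
        assert achieved_rejections(strata, w, 0.1) >= achieved_rejections(strata, np.ones(6), 0.1)
        counts = np.array([60] * 6)
        assert (w @ counts) / counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_tv_regularization_excludes_rough_vectors(self, rng):
        a = 0.5 + 0.5 * rng.random(200)
        b = np.concatenate([rng.random(150), rng.random(50) * 1e-6])
        w_free = learn_stratum_weights([a, b], alpha=0.1)
        w_tv = learn_stratum_weights([a, b], alpha=0.1, tv_lambda=0.5)
        assert abs(np.diff(w_tv)).sum() <= 0.5 + 1e-9
        assert abs(np.diff(w_free)).sum() > 0.5

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError):
            learn_stratum_weights([np.array([0.1]), np.array([])], alpha=0.1)


class TestIHW:
    def test_constant_covariate_reduces_to_bh(self, rng):
        p = rng.random(2000) ** 2
        _, bh_rej = bh_rejections(p, 0.1)
        res = ihw(p, np.zeros(2000), alpha=0.1, n_bins=4, seed=3)
        assert res.n_bins_ == 1
        np.testing.assert_array_equal(res.rejected_, bh_rej)

    def test_nbins_one_reduces_to_bh_every_alpha(self, rng):
        p = rng.random(1000) ** 3
        x = rng.random(1000)
        for alpha in (0.05, 0.1, 0.2, 0.3):
            res = ihw(p, x, alpha=alpha, n_bins=1, seed=0)
            _, bh_rej = bh_rejections(p, alpha)
            np.testing.assert_array_equal(res.rejected_, bh_rej)
            np.testing.assert_array_equal(res.weight_of_, np.ones(1000))

    def test_fold_budget_exact(self, rng):
        p = np.concatenate([rng.random(3000), rng.random(600) * 1e-3])
        x = np.concatenate([rng.random(3000), 0.8 + 0.2 * rng.random(600)])
        res = ihw(p, x, alpha=0.1, n_bins=3, n_folds=5, seed=1)
        for l in range(5):
            assert res.weight_of_[res.fold_of_ == l].mean() == pytest.approx(1.0, abs=1e-9)

    def test_cross_weighting_audit_weights_recomputable_from_complement(self, rng):
        """Weights stored for fold l match an instrumented recomputation from
        the complement folds' p-values only."""
        p = np.concatenate([rng.random(1500), rng.random(500) * 1e-2])
        x = np.concatenate([rng.random(1500), 0.9 + 0.1 * rng.random(500)])
        res = ihw(p, x, alpha=0.1, n_bins=2, n_folds=4, seed=9)
        for l in range(4):
            train = res.fold_of_ != l
            train_p = [p[train & (res.stratum_of_ == g)] for g in range(res.n_bins_)]
            w = learn_stratum_weights(train_p, alpha=0.1)
            hold_counts = np.bincount(res.stratum_of_[res.fold_of_ == l], minlength=res.n_bins_)
            w = w * hold_counts.sum() / (w @ hold_counts)
            np.testing.assert_allclose(res.weights_[l], w, atol=1e-12)

    def test_weight_applied_to_hypothesis_never_depends_on_its_pvalue(self, rng):
        p = np.concatenate([rng.random(800), rng.random(200) * 1e-2])
        x = rng.random(1000)
        res = ihw(p, x, alpha=0.1, n_bins=2, n_folds=3, seed=4)
        i = 17
        p2 = p.copy()
        p2[i] = 0.9876  # arbitrary replacement in [0,1]
        res2 = ihw(p2, x, alpha=0.1, n_bins=2, n_folds=3, seed=4)
        l = res.fold_of_[i]
        assert res2.fold_of_[i] == l  # split depends only on covariate + seed
        np.testing.assert_array_equal(res.weights_[l], res2.weights_[l])
        assert res.weight_of_[i] == res2.weight_of_[i]

    def test_monotone_alpha_for_fixed_weights(self, rng):
        p = rng.random(500) ** 2
        from rvprior.weighting import _weighted_bh_pass

        w = np.where(rng.random(500) < 0.5, 0.5, 1.5)
        wp = p / w
        _, rej_small = _weighted_bh_pass(wp, 0.05)
        _, rej_big = _weighted_bh_pass(wp, 0.2)
        assert np.all(rej_big[rej_small])  # rejection set grows with alpha

    def test_small_m_falls_back_to_single_stratum(self, rng, caplog):
        p = rng.random(8)
        res = ihw(p, rng.random(8), alpha=0.1, n_bins=4, n_folds=5, seed=0)
        assert res.n_bins_ == 1

    def test_missing_pvalues_dropped_by_wrapper(self, rng):
        p = rng.random(100)
        p[[3, 50]] = np.nan
        res = ihw(p, rng.random(100), alpha=0.1, n_bins=1, seed=0)
        assert res.m_ == 98

    def test_auto_bins_rule(self):
        assert auto_n_bins(100) == 1
        assert auto_n_bins(4500) == 3
        assert auto_n_bins(19000) == 10
        assert auto_n_bins(1_000_000) == 10

    def test_estimator_clones_with_sklearn(self):
        from sklearn.base import clone

        est = IndependentHypothesisWeighting(alpha=0.2, n_bins=3)
        est2 = clone(est)
        assert est2.get_params()["alpha"] == 0.2


class TestShuffledControlAndHistogram:
    def test_zero_shuffles_empty(self, rng):
        out = shuffled_covariate_control(rng.random(50), rng.random(50), n_shuffles=0)
        assert out.size == 0

    def test_same_seed_identical_sequence(self, rng):
        p, x = rng.random(300), rng.random(300)
        a = shuffled_covariate_control(p, x, n_shuffles=4, alpha=0.2, seed=11, n_bins=2)
        b = shuffled_covariate_control(p, x, n_shuffles=4, alpha=0.2, seed=11, n_bins=2)
        np.testing.assert_array_equal(a, b)

    def test_histogram_conserves_counts_and_null_is_flat(self, rng):
        m = 30_000
        p, x = rng.random(m), rng.random(m)
        counts, first_bin = stratified_pvalue_histogram(p, x)
        assert counts.to_numpy().sum() == m
        from scipy.stats import chisquare

        assert chisquare(first_bin.to_numpy()).pvalue > 0.01

    def test_informative_covariate_increases_first_bin(self):
        cfg = SimConfig(seed=5)
        _, truth = simulate_loci(cfg)
        tbl, _ = simulate_rvas_pvalues(truth, cfg)
        counts, fb = stratified_pvalue_histogram(tbl["p"], truth.propensity)
        assert fb["low"] < fb["medium"] < fb["high"]
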