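"""Event classification and null-model statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import trijunction as tj
from trijunction.inference import chi_square_gof

from conftest import PIXEL_SIZE


def exact_multinomial_p(observed, probs):
    """Full tail enumeration over all outcomes of size n into 3 cells."""
    n = int(np.sum(observed))
    probs = np.asarray(probs, dtype=float)
    outs = [(a, b, n - a - b)
            for a in range(n + 1) for b in range(n - a + 1)]
    logp = stats.multinomial.logpmf(np.array(outs), n, probs)
    l_obs = stats.multinomial.logpmf(np.asarray(observed), n, probs)
    return float(np.exp(logp[logp <= l_obs + 1e-9]).sum())


def wilson_interval(k, n, z=1.959963984540054):
    ph = k / n
    den = 1 + z ** 2 / n
    ctr = (ph + z ** 2 / (2 * n)) / den
    hw = z * np.sqrt(ph * (1 - ph) / n + z ** 2 / (4 * n ** 2)) / den
    return ctr - hw, ctr + hw


class TestClassifyEvents:
    def test_tri_centroid_is_tri_at_any_radius(self, junctions_lab50):
        pt = junctions_lab50.tri_points.iloc[0]
        ev = pd.DataFrame({"event_id": [0], "x_um": [pt["x_um"]],
                           "y_um": [pt["y_um"]]})
        for r in (0.0, 1.0, 3.0, 6.0):
            cmap = tj.build_category_map(junctions_lab50, r)
            out = tj.classify_events(ev, cmap)
            assert out["observed_category"].iloc[0] == "TRI"

    def test_far_interior_event_is_body(self, junctions_lab50):
        j = junctions_lab50
        from scipy import ndimage
        d = np.minimum(
            ndimage.distance_transform_edt(~j.tri_mask(), sampling=PIXEL_SIZE),
            ndimage.distance_transform_edt(~j.bi_mask(), sampling=PIXEL_SIZE))
        r, c = np.unravel_index(np.argmax(d), d.shape)
        ev = pd.DataFrame({"event_id": [0],
                           "x_um": [(c + 0.5) * PIXEL_SIZE],
                           "y_um": [(r + 0.5) * PIXEL_SIZE]})
        cmap = tj.build_category_map(j, d[r, c] / 2)
        assert tj.classify_events(ev, cmap)["observed_category"].iloc[0] == "BODY"

    def test_out_of_bounds_flagged_not_fatal(self, junctions_lab50):
        cmap = tj.build_category_map(junctions_lab50, 1.0)
        ev = pd.DataFrame({"event_id": [0, 1],
                           "x_um": [-5.0, 10.0], "y_um": [10.0, 10.0]})
        out = tj.classify_events(ev, cmap)
        assert out["unclassifiable"].iloc[0] == "out_of_bounds"
        assert out["unclassifiable"].iloc[1] == ""

    def test_round_trip_recovers_generating_category(self, junctions_lab50):
        r = 2.0
        cmap = tj.build_category_map(junctions_lab50, r)
        ev = tj.generate_events(cmap, tj.EventModel(
            kind="category_probs", probs=(0.4, 0.3, 0.3), n_events=2000,
            seed=3))
        out = tj.classify_events(ev, cmap)
        agree = (out["observed_category"] == out["true_category"]).mean()
        assert agree >= 0.99

    def test_order_invariance(self, junctions_lab50):
        cmap = tj.build_category_map(junctions_lab50, 1.0)
        ev = tj.generate_events(cmap, tj.EventModel(kind="uniform",
                                                    n_events=100, seed=5))
        shuffled = ev.sample(frac=1, random_state=0).reset_index(drop=True)
        a = tj.classify_events(ev, cmap)["observed_category"].value_counts()
        b = tj.classify_events(shuffled, cmap)[
            "observed_category"].value_counts()
        assert a.to_dict() == b.to_dict()


class TestMultinomialGof:
    def test_mode_of_null_gives_p_near_one(self):
        p = tj.multinomial_gof([5, 15, 80], (0.05, 0.15, 0.80),
                               n_mc=9999, seed=1)
        assert p > 0.9

    def test_extreme_observation_agrees_with_enumeration(self):
        obs, probs = (60, 20, 20), (0.05, 0.15, 0.80)
        p_exact = exact_multinomial_p(obs, probs)
        p_mc = tj.multinomial_gof(obs, probs, n_mc=9999, seed=0)
        assert p_mc < 0.001
        assert abs(p_mc - p_exact) <= 2 / (9999 + 1)

    def test_moderate_observation_agrees_with_enumeration(self):
        obs, probs = (9, 4, 7), (0.2, 0.3, 0.5)
        p_exact = exact_multinomial_p(obs, probs)
        p_mc = tj.multinomial_gof(obs, probs, n_mc=99999, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / 99999)
        assert abs(p_mc - p_exact) <= 4 * se + 1e-5

    def test_deterministic_per_seed(self):
        args = ([10, 5, 85], (0.1, 0.1, 0.8))
        assert (tj.multinomial_gof(*args, n_mc=999, seed=7)
                == tj.multinomial_gof(*args, n_mc=999, seed=7))

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tj.multinomial_gof([0, 0, 0], (0.3, 0.3, 0.4), n_mc=999, seed=0)

    def test_zero_prob_category_with_count_rejects(self):
        p = tj.multinomial_gof([10, 45, 45], (0.0, 0.5, 0.5),
                               n_mc=999, seed=0)
        assert p == pytest.approx(1 / 1000)

    def test_chi_square_agrees_at_large_n(self):
        obs, probs = (300, 290, 410), (0.3, 0.3, 0.4)
        p_mc = tj.multinomial_gof(obs, probs, n_mc=9999, seed=3)
        p_chi = chi_square_gof(obs, probs)
        assert abs(p_mc - p_chi) < 0.1


class TestPerCategoryBinomial:
    def test_saturated_category(self):
        res = tj.per_category_binomial([100, 0, 0], (1.0, 0.0, 0.0))
        assert res[0].p_value == 1.0
        assert res[0].enrichment == 1.0

    def test_exact_binomial_matches_tail_sum_oracle(self):
        res = tj.per_category_binomial([60, 20, 20], (0.25, 0.25, 0.50))
        pm = stats.binom.pmf(np.arange(101), 100, 0.25)
        p_oracle = pm[pm <= pm[60] * (1 + 1e-12)].sum()
        assert res[0].p_value < 1e-9
        assert res[0].p_value == pytest.approx(p_oracle, abs=1e-9)
        assert res[0].enrichment == pytest.approx(2.4)

    def test_wilson_interval_matches_closed_form(self):
        res = tj.per_category_binomial([60, 20, 20], (0.25, 0.25, 0.50))
        lo, hi = wilson_interval(60, 100)
        assert res[0].ci95[0] == pytest.approx(lo, abs=1e-9)
        assert res[0].ci95[1] == pytest.approx(hi, abs=1e-9)
        assert (round(res[0].ci95[0], 2), round(res[0].ci95[1], 2)) \
            == (0.50, 0.69)

    def test_bh_adjustment_bounds(self):
        res = tj.per_category_binomial([30, 30, 40], (0.2, 0.3, 0.5))
        for r in res:
            assert r.adjusted_p >= r.p_value - 1e-12
            assert r.adjusted_p <= 1.0


class TestStatisticalInvariants:
    from hypothesis import given, settings, strategies as st

    @given(counts=st.lists(st.integers(0, 60), min_size=3, max_size=3),
           w=st.lists(st.floats(0.05, 1.0), min_size=3, max_size=3))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_binomial_results_are_coherent(self, counts, w):
        """For any counts and null probabilities: p-values in [0, 1],
        BH-adjusted >= raw, Wilson CI brackets the observed fraction,
        enrichment consistent with fraction/probability."""
        if sum(counts) == 0:
            counts[0] = 1
        probs = np.array(w) / np.sum(w)
        res = tj.per_category_binomial(counts, probs)
        n = sum(counts)
        for r, k, p0 in zip(res, counts, probs):
            assert 0.0 <= r.p_value <= 1.0
            assert r.p_value - 1e-12 <= r.adjusted_p <= 1.0
            assert r.ci95[0] - 1e-12 <= k / n <= r.ci95[1] + 1e-12
            assert r.enrichment == pytest.approx((k / n) / p0)

    @given(counts=st.lists(st.integers(0, 40), min_size=3, max_size=3))
    @settings(max_examples=15, derandomize=True, deadline=None)
    def test_mc_p_value_bounded_and_positive(self, counts):
        if sum(counts) == 0:
            counts[2] = 5
        p = tj.multinomial_gof(counts, (0.2, 0.3, 0.5), n_mc=999, seed=1)
        assert 1 / 1000 <= p <= 1.0


class TestRunNullAnalysis:
    def test_no_events_rejected(self, junctions_lab50):
        with pytest.raises(ValueError):
            tj.run_null_analysis(pd.DataFrame(columns=["event_id", "x_um",
                                                       "y_um"]),
                                 junctions_lab50, [1.0], seed=0)

    def test_result_counts_sum_to_events(self, junctions_lab50):
        cmap = tj.build_category_map(junctions_lab50, 2.0)
        ev = tj.generate_events(cmap, tj.EventModel(kind="uniform",
                                                    n_events=60, seed=1))
        res = tj.run_null_analysis(ev, junctions_lab50, [1.0, 3.0],
                                   n_mc=999, seed=0)
        assert len(res) == 2
        for r in res:
            assert sum(r.observed.values()) + r.n_unclassifiable == 60

    def test_consistency_p_shrinks_with_n(self, junctions_lab50):
        """With a fixed junction-tropic composition the global p-value
        falls toward 0 as the number of events grows."""
        cmap = tj.build_category_map(junctions_lab50, 6.0)
        pvals = []
        for n in (26, 100, 1000):
            ev = tj.generate_events(cmap, tj.EventModel(
                kind="category_probs", probs=(0.6, 0.3, 0.1), n_events=n,
                seed=11))
            res = tj.run_null_analysis(ev, junctions_lab50, [6.0],
                                       n_mc=999, seed=5)
            pvals.append(res[0].global_p)
        assert pvals[2] == pytest.approx(1 / 1000)
        assert pvals[0] <= 0.05

    def test_enrichment_near_one_under_null(self, junctions_lab50):
        """Uniform events give enrichment ratios compatible with 1."""
        cmap = tj.build_category_map(junctions_lab50, 3.0)
        ev = tj.generate_events(cmap, tj.EventModel(kind="uniform",
                                                    n_events=4000, seed=21))
        res = tj.run_null_analysis(ev, junctions_lab50, [3.0],
                                   n_mc=999, seed=2)[0]
        for c in res.per_category:
            se = np.sqrt(c.expected_prob * (1 - c.expected_prob) / 4000)
            assert abs(c.observed / 4000 - c.expected_prob) <= 4 * se

    def test_deterministic_per_seed(self, junctions_lab50):
        cmap = tj.build_category_map(junctions_lab50, 2.0)
        ev = tj.generate_events(cmap, tj.EventModel(kind="uniform",
                                                    n_events=40, seed=9))
        a = tj.run_null_analysis(ev, junctions_lab50, [2.0], n_mc=999, seed=3)
        b = tj.run_null_analysis(ev, junctions_lab50, [2.0], n_mc=999, seed=3)
        assert a[0].global_p == b[0].global_p
        assert a[0].observed == b[0].observed
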