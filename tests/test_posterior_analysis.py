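import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crowdasym.bayes_model import PosteriorDraws, fixed_effect_names, fixed_effect_row
from crowdasym.design_core import RANDOM_EFFECTS, ConditionCell
from crowdasym.posterior_analysis import (
    AnalysisConfig,
    cell_threshold_draws,
    contrast_ratio,
    crowding_factor,
    exceedance,
    hdi,
    ioa_draws,
    ioa_table,
    meridian_contrast,
    simulate_population,
)


def hdi_oracle(samples, mass):
    """Exhaustive shortest-window search, written independently of hdi()."""
    s = sorted(float(v) for v in samples)
    n = len(s)
    m = math.ceil(mass * n)
    if m >= n:
        return s[0], s[-1]
    best = None
    for i in range(n - m + 1):
        width = s[i + m - 1] - s[i]
        if best is None or width < best[0]:
            best = (width, s[i], s[i + m - 1])
    return best[1], best[2]


def synthetic_draws(beta, tau=None, sigma=None, participants=("p1",)):
    """Wrap explicit coefficient draws in a PosteriorDraws container."""
    beta = np.asarray(beta, dtype=float)
    if beta.ndim == 2:
        beta = beta[None]  # one chain
    c, d, _ = beta.shape
    r = len(RANDOM_EFFECTS)
    tau = np.zeros((c, d, r)) if tau is None else np.asarray(tau, float).reshape(c, d, r)
    sigma = np.full((c, d), 0.1) if sigma is None else np.asarray(sigma, float).reshape(c, d)
    return PosteriorDraws(
        beta=beta,
        b=np.zeros((c, d, len(participants), r)),
        tau=tau,
        sigma=sigma,
        fixed_names=fixed_effect_names(),
        random_names=list(RANDOM_EFFECTS),
        participants=list(participants),
        seed=0,
    )


class TestHdi:
    def test_documented_example(self):
        assert hdi([1, 2, 3, 4, 5], 0.6) == (1.0, 3.0)

    def test_matches_oracle_on_random_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n = int(rng.integers(2, 2000))
            kind = rng.integers(0, 3)
            if kind == 0:
                s = rng.normal(0, 1, n)
            elif kind == 1:
                s = rng.lognormal(0, 0.7, n)
            else:
                s = rng.uniform(-5, 5, n)
            for mass in (0.53, 0.75, 0.97):
                assert hdi(s, mass) == hdi_oracle(s, mass)

    def test_symmetric_sample_close_to_quantile_interval(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 200_000)
        lo, hi = hdi(s, 0.97)
        q_lo, q_hi = np.quantile(s, [0.015, 0.985])
        assert lo == pytest.approx(q_lo, abs=0.05)
        assert hi == pytest.approx(q_hi, abs=0.05)

    def test_degenerate_samples(self):
        assert hdi([2.0, 2.0, 2.0], 0.5) == (2.0, 2.0)
        with pytest.raises(ValueError):
            hdi([], 0.5)
        with pytest.raises(ValueError):
            hdi([1.0, 2.0], 1.5)


class TestExceedance:
    def test_strict_inequality(self):
        assert exceedance(np.full(100, 2.0), 1.5) == 1.0
        assert exceedance(np.full(100, 1.0), 1.0) == 0.0

    def test_median_criterion_on_known_distribution(self):
        rng = np.random.default_rng(2)
        s = rng.normal(3.0, 1.0, 100_000)
        assert exceedance(s, 3.0) == pytest.approx(0.5, abs=0.01)

    @settings(derandomize=True, max_examples=30)
    @given(shift=st.floats(-2, 2))
    def test_monotone_nonincreasing_in_criterion(self, shift):
        rng = np.random.default_rng(0)
        s = rng.normal(shift, 1.0, 500)
        probs = [exceedance(s, c) for c in np.linspace(-3, 3, 13)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestDerivedRatios:
    def test_zero_coefficients_give_unit_threshold(self):
        draws = synthetic_draws(np.zeros((5, 36)))
        t = cell_threshold_draws(draws, ConditionCell("blocked", "up", "none"))
        assert np.allclose(t, 1.0)

    def test_single_active_coefficient(self):
        beta = np.zeros((1, 36))
        beta[0, fixed_effect_names().index("loc_up")] = 1.0
        draws = synthetic_draws(beta)
        t = cell_threshold_draws(draws, ConditionCell("blocked", "up", "none"))
        assert t[0] == pytest.approx(np.e)

    def test_crowding_factor_unity_when_flanked_equals_unflanked(self):
        # flanker coefficients zero -> flanked thresholds equal unflanked
        beta = np.zeros((4, 36))
        beta[:, fixed_effect_names().index("loc_left")] = 0.7
        draws = synthetic_draws(beta)
        cf = crowding_factor(draws, "blocked", "left", "inward")
        assert np.allclose(cf, 1.0)

    def test_crowding_factor_rejects_unflanked(self):
        draws = synthetic_draws(np.zeros((2, 36)))
        with pytest.raises(ValueError):
            crowding_factor(draws, "blocked", "up", "none")

    def test_ioa_equals_cf_ratio_per_draw(self, small_fit):
        _, draws = small_fit
        for design, location in (("blocked", "up"), ("random", "left")):
            ioa = ioa_draws(draws, design, location)
            ratio = crowding_factor(draws, design, location, "outward") / crowding_factor(
                draws, design, location, "inward"
            )
            assert np.allclose(ioa, ratio, rtol=1e-12)

    def test_ratios_invariant_to_global_rescaling(self, small_fit):
        """Adding a constant to every location intercept rescales all
        thresholds but leaves every ratio statistic unchanged."""
        _, draws = small_fit
        shifted = synthetic_draws(draws.beta.copy(), tau=draws.tau, sigma=draws.sigma,
                                  participants=draws.participants)
        for loc in ("up", "down", "left", "right"):
            shifted.beta[..., fixed_effect_names().index(f"loc_{loc}")] += 1.3
        base = ioa_draws(draws, "precued", "right")
        scaled = ioa_draws(shifted, "precued", "right")
        assert np.allclose(base, scaled, rtol=1e-10)

    def test_ioa_table_layout(self, small_fit):
        _, draws = small_fit
        table = ioa_table(draws)
        assert len(table) == 12
        assert set(table.columns) >= {
            "design", "location", "p_gt_1_5", "hdi97_lo", "hdi53_lo",
            "median", "hdi53_hi", "hdi97_hi",
        }
        # 53% interval nested inside the 97% interval
        assert (table["hdi53_lo"] >= table["hdi97_lo"]).all()
        assert (table["hdi53_hi"] <= table["hdi97_hi"]).all()


class TestContrasts:
    def test_identical_pools_rejected(self, small_fit):
        _, draws = small_fit
        with pytest.raises(ValueError):
            contrast_ratio(draws, [("blocked", "up")], [("blocked", "up")])

    def test_known_location_difference_recovered(self):
        """IOA_left = 3, IOA_right = 2 built directly into the coefficients:
        the left/right contrast must sit at 1.5."""
        names = fixed_effect_names()
        beta = np.zeros((50, 36))
        beta[:, names.index("fl_outward")] = np.log(2.0)  # IOA 2 at reference
        beta[:, names.index("loc_left:fl_outward")] = np.log(3.0) - np.log(2.0)
        draws = synthetic_draws(beta)
        out = contrast_ratio(draws, [("blocked", "left")], [("blocked", "right")])
        assert out["median"] == pytest.approx(1.5, rel=1e-9)
        assert out["p_gt_1"] == 1.0

    def test_meridian_contrast_pools_geometrically(self):
        names = fixed_effect_names()
        beta = np.zeros((10, 36))
        beta[:, names.index("fl_outward")] = np.log(2.0)
        # boost left IOA to 8 -> horizontal pool sqrt(2*8)=4, vertical 2
        beta[:, names.index("loc_left:fl_outward")] = np.log(8.0) - np.log(2.0)
        draws = synthetic_draws(beta)
        res = meridian_contrast(draws, "blocked")
        assert res["median"] == pytest.approx(2.0, rel=1e-9)


class TestPopulationSimulation:
    def test_zero_variance_collapses_to_average_observer(self, small_fit):
        _, draws = small_fit
        frozen = synthetic_draws(draws.beta.copy(), tau=np.zeros_like(draws.tau),
                                 sigma=draws.sigma, participants=draws.participants)
        sim = simulate_population(frozen, AnalysisConfig(n_simulated_participants=400, rng_seed=3))
        # every simulated participant's IOA is an average-observer IOA,
        # so the simulated spread cannot exceed the posterior spread
        for design, location in (("blocked", "up"), ("random", "left")):
            post = np.log(ioa_draws(frozen, design, location))
            entry = sim["per_cell"][f"{design}/{location}"]
            assert entry["var_log"] <= post.var() * 1.5 + 1e-12

    def test_deterministic_under_seed(self, small_fit):
        _, draws = small_fit
        cfg = AnalysisConfig(n_simulated_participants=300, rng_seed=11)
        assert simulate_population(draws, cfg) == simulate_population(draws, cfg)

    def test_population_spread_tracks_varying_effect_sd(self):
        """Simulated-participant IOA variance approximates the generative
        variance implied by the flanker varying-effect SDs."""
        names = fixed_effect_names()
        beta = np.zeros((200, 36))
        beta[:, names.index("fl_outward")] = np.log(2.5)
        tau = np.zeros((1, 200, len(RANDOM_EFFECTS)))
        i_in = RANDOM_EFFECTS.index("fl_inward")
        i_out = RANDOM_EFFECTS.index("fl_outward")
        tau[..., i_in] = 0.2
        tau[..., i_out] = 0.2
        draws = synthetic_draws(beta, tau=tau)
        sim = simulate_population(draws, AnalysisConfig(n_simulated_participants=4000, rng_seed=5))
        var = sim["per_cell"]["blocked/up"]["var_log"]
        expected = 2 * 0.2**2  # log IOA = log(2.5) + b_out - b_in
        assert expected / 2 < var < expected * 2
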