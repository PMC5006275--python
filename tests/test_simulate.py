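"""Trial data generators: sampling distributions, invariants, edge rules."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import tvsmart as tv
from tvsmart.design import DesignSpec
from tvsmart.simulate import GenParams, sample_truncated_weibull


class TestTruncatedWeibull:
    def test_shape_one_mean_is_shifted_exponential(self):
        # memorylessness: truncation at t00 just shifts an exponential
        rng = np.random.default_rng(1)
        x = sample_truncated_weibull(1.0, 2.0, 0.1, rng, size=100_000)
        se = 2.0 / np.sqrt(x.size)
        assert abs(x.mean() - 2.1) < 3 * se
        assert x.min() > 0.1

    def test_matches_conditional_cdf_shape_two(self):
        """Goodness of fit against the closed-form conditional Weibull CDF."""
        shape, scale, t00 = 2.0, 1.0, 0.5
        rng = np.random.default_rng(2)
        x = sample_truncated_weibull(shape, scale, t00, rng, size=10_000)
        s0 = np.exp(-((t00 / scale) ** shape))

        def cdf(t):
            return 1.0 - np.exp(-((t / scale) ** shape)) / s0

        assert stats.kstest(x, cdf).pvalue > 0.01

    @given(
        shape=st.floats(0.3, 5.0),
        scale=st.floats(0.1, 10.0),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=40, deadline=None)
    def test_draws_always_exceed_truncation_point(self, shape, scale, seed):
        rng = np.random.default_rng(seed)
        x = sample_truncated_weibull(shape, scale, 0.2, rng, size=64)
        assert np.all(x > 0.2) and np.all(np.isfinite(x))

    def test_nonpositive_parameters_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_truncated_weibull(0.0, 1.0, 0.1, rng)
        with pytest.raises(ValueError):
            sample_truncated_weibull(1.0, -1.0, 0.1, rng)


class TestWeibullGenerator:
    def test_trial_satisfies_all_structural_invariants(self, table1_data, table1):
        tv.validate_trialdata(table1_data, table1.design)
        d = table1_data
        assert 0.0 < d["delta"].mean() < 1.0
        # responder rule honoured exactly on both sides
        drop = d["Y0"] - d["Y1"]
        assert (drop[d["delta"] == 1] >= 9.0).all()
        assert (drop[d["delta"] == 0] < 9.0).all()
        assert np.allclose(d["T2"], d["T1"] + 1.0)

    def test_degenerate_noise_gives_exact_baseline(self, table1):
        p = dataclasses.replace(table1.params, sigma_b=0.0, sigma0=0.0)
        rng = tv.replicate_rng(0, 0)
        d = tv.simulate_trial_weibull(table1.design, p, 200, rng)
        assert np.allclose(d["Y0"], p.beta00)

    def test_unequal_allocation_frequencies(self):
        """Fig.-2 probabilities: 0.4/0.6 first stage, 0.55/0.45 among
        non-responders; empirical frequencies within 3 binomial SEs."""
        cfg = tv.load_scenario("table5")
        rng = tv.replicate_rng(3, 0)
        d = tv.simulate_trial_weibull(cfg.design, cfg.params, 4000, rng)
        n = len(d)
        p_b = (d["A1"] == 1).mean()
        assert abs(p_b - 0.6) < 3 * np.sqrt(0.6 * 0.4 / n)
        nr = d[d["delta"] == 0]
        p_int = (nr["A2NR"] == 1).mean()
        assert abs(p_int - 0.45) < 3 * np.sqrt(0.45 * 0.55 / len(nr))
        assert (d["A2R"] == 0).all()  # responders never re-randomized here

    def test_bit_identical_reproducibility(self, table1):
        a = tv.simulate_trial(table1.design, table1.params, 300, tv.replicate_rng(9, 4))
        b = tv.simulate_trial(table1.design, table1.params, 300, tv.replicate_rng(9, 4))
        pd.testing.assert_frame_equal(a, b)

    def test_response_rate_monotone_in_event_scale(self, table1):
        """Smaller scale intercept => faster response => more responders."""
        rng1, rng2 = tv.replicate_rng(5, 0), tv.replicate_rng(5, 1)
        fast = dataclasses.replace(table1.params, gamma0=-2.5)
        slow = dataclasses.replace(table1.params, gamma0=-0.5)
        r_fast = tv.simulate_trial_weibull(table1.design, fast, 4000, rng1)["delta"].mean()
        r_slow = tv.simulate_trial_weibull(table1.design, slow, 4000, rng2)["delta"].mean()
        assert r_fast > r_slow

    def test_arms_exchangeable_without_event_covariates(self, table1):
        """With gamma1 = alpha = 0 the response-time law is arm-free."""
        p = dataclasses.replace(table1.params, gamma1=0.0, alpha=0.0)
        d = tv.simulate_trial_weibull(table1.design, p, 10_000, tv.replicate_rng(6, 0))
        resp = d[d["delta"] == 1]
        t_m = resp.loc[resp["A1"] == -1, "T1"]
        t_b = resp.loc[resp["A1"] == 1, "T1"]
        assert stats.ks_2samp(t_m, t_b).pvalue > 0.01
        p_m = d.loc[d["A1"] == -1, "delta"].mean()
        p_b = d.loc[d["A1"] == 1, "delta"].mean()
        pbar = d["delta"].mean()
        assert abs(p_m - p_b) < 3 * np.sqrt(pbar * (1 - pbar) * (2 / (len(d) / 2)))

    def test_standard_variant_assesses_response_at_t10(self, table1):
        d = tv.simulate_trial_weibull(
            table1.design.standard_analog(), table1.params, 800, tv.replicate_rng(7, 0)
        )
        assert (d["T1"] == 1.0).all()
        drop = d["Y0"] - d["Y1"]
        assert ((drop >= 9.0) == (d["delta"] == 1)).all()


def boundary_design(**kw):
    base = dict(
        variant="full_rerand_timevarying",
        responder_rule="relative_drop",
        threshold=0.4,
        t00=0.1,
        t10=1.0,
    )
    base.update(kw)
    return DesignSpec(**base)


class TestBoundaryGenerator:
    def test_crossing_time_hand_value(self):
        """Deterministic check: b=0, e1=0, Y0=2, A1=+1 crossing at 0.74."""
        d = boundary_design(p_stage1=1 - 1e-12)
        p = GenParams(
            beta00=2.0, beta01=-2.0, beta11=-0.5, beta31=5.0,
            sigma_b=0.0, sigma0=0.0, sigma1=0.0, sigma2=0.0,
        )
        out = tv.simulate_trial_boundary(d, p, 50, tv.replicate_rng(0, 0))
        assert np.allclose(out["T1"], 0.74)
        assert (out["delta"] == 1).all()
        # Y1 equals the boundary value (1 - 0.4) * Y0 at an interior crossing
        assert np.allclose(out["Y1"], 0.6 * 2.0)

    def test_early_crossings_clamped_to_monitoring_start(self):
        # crossing before t00: target already passed at the first look
        d = boundary_design(p_stage1=1 - 1e-12)
        p = GenParams(beta00=2.0, beta01=-2.0, beta11=-0.5, beta31=100.0,
                      sigma_b=0.0, sigma0=0.0, sigma1=0.0, sigma2=0.0)
        out = tv.simulate_trial_boundary(d, p, 20, tv.replicate_rng(0, 0))
        assert (out["T1"] == 0.1).all() and (out["delta"] == 1).all()

    def test_late_crossings_censored_at_t10(self):
        d = boundary_design(p_stage1=1 - 1e-12)
        p = GenParams(beta00=2.0, beta01=-10.0, beta11=0.0, beta31=5.0,
                      sigma_b=0.0, sigma0=0.0, sigma1=0.0, sigma2=0.0)
        out = tv.simulate_trial_boundary(d, p, 20, tv.replicate_rng(0, 0))
        assert (out["T1"] == 1.0).all() and (out["delta"] == 0).all()

    def test_literal_clamp_reproduces_printed_rule(self):
        # audit mode: late crossings mapped to t00 instead of t10
        d = boundary_design(p_stage1=1 - 1e-12)
        p = GenParams(beta00=2.0, beta01=-10.0, beta11=0.0, beta31=5.0,
                      sigma_b=0.0, sigma0=0.0, sigma1=0.0, sigma2=0.0)
        out = tv.simulate_trial_boundary(
            d, p, 20, tv.replicate_rng(0, 0), literal_clamp=True
        )
        assert (out["T1"] == 0.1).all() and (out["delta"] == 0).all()

    def test_alternate_scenario_invariants_hold(self):
        cfg = tv.load_scenario("table9")
        d = tv.simulate_trial(
            cfg.design, cfg.params, 1000, tv.replicate_rng(1, 0), mechanism="boundary"
        )
        tv.validate_trialdata(d, cfg.design)
        # responder rule holds where the crossing is interior
        interior = (d["T1"] > 0.1) & (d["delta"] == 1)
        assert interior.any()
        assert np.allclose(d.loc[interior, "Y1"], 0.6 * d.loc[interior, "Y0"])

    def test_zero_slope_has_no_crossing(self):
        p = GenParams(beta31=0.0)
        with pytest.raises(ValueError, match="beta31"):
            tv.simulate_trial_boundary(boundary_design(), p, 10, tv.replicate_rng(0, 0))

    def test_requires_relative_rule(self):
        with pytest.raises(ValueError, match="relative_drop"):
            tv.simulate_trial_boundary(
                DesignSpec(), GenParams(), 10, tv.replicate_rng(0, 0)
            )


class TestIO:
    def test_round_trip_through_delimited_text(self, small_data, table1, tmp_path):
        path = tmp_path / "trial.csv"
        tv.write_trialdata(small_data, path)
        back = tv.read_trialdata(path)
        assert "b" not in back.columns  # latent dropped by default
        pd.testing.assert_frame_equal(
            back, small_data.drop(columns="b"), check_exact=False, rtol=1e-12
        )
        tv.validate_trialdata(back, table1.design)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"id": [1], "Y0": [2.0]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing"):
            tv.read_trialdata(path)
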