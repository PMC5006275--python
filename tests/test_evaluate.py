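"""Replication engine, AI means, power selection and trial cost."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import tvsmart as tv
from tvsmart.design import DesignSpec, EmbeddedAI
from tvsmart.simulate import GenParams


def naive_ai_means(data, design):
    """Independent one-pass re-aggregation oracle."""
    sums = {str(ai): [0.0, 0] for ai in tv.enumerate_embedded_ais(design)}
    for _, rec in data.iterrows():
        for ai in tv.enumerate_embedded_ais(design):
            if tv.subject_consistent_with_ai(rec, ai, design):
                s = sums[str(ai)]
                s[0] += rec["Y2"]
                s[1] += 1
    return pd.Series(
        {k: (v[0] / v[1] if v[1] else np.nan) for k, v in sums.items()}
    )


class TestSimulatedAiMeans:
    def test_equals_naive_reaggregation(self, small_data, table1):
        got = tv.simulated_ai_means(small_data, table1.design)
        want = naive_ai_means(small_data, table1.design)
        pd.testing.assert_series_equal(got, want, check_names=False, atol=1e-12)

    def test_constant_model_gives_constant_means(self):
        # no noise, no effects: every AI mean equals the final intercept
        d = DesignSpec(threshold=-100.0)  # responders trivially satisfy the rule
        p = GenParams(
            beta02=3.5, beta12=0, beta22=0, beta23=0, beta32=0,
            sigma_b=0, sigma0=0, sigma1=0, sigma2=0, gamma0=-10.0,
        )
        data = tv.simulate_trial(d, p, 400, tv.replicate_rng(0, 0))
        assert (data["delta"] == 1).all()  # gamma0=-10 makes response immediate
        means = tv.simulated_ai_means(data, d)
        assert np.allclose(means.dropna(), 3.5)

    def test_empty_ai_reported_missing_not_zero(self, table1):
        data = tv.simulate_trial(table1.design, table1.params, 30, tv.replicate_rng(1, 0))
        data = data[data["A1"] == 1]  # remove the whole medication arm
        means = tv.simulated_ai_means(data, table1.design)
        assert means[[k for k in means.index if k.startswith("(-1")]].isna().all()
        assert means[[k for k in means.index if k.startswith("(+1")]].notna().all()


class FakeFit:
    def __init__(self, params):
        self.params = pd.Series(params)


class TestEstimatedAiMeans:
    def test_hand_computed_four_subject_dataset(self):
        design = DesignSpec()
        data = pd.DataFrame(
            {
                "id": [0, 1, 2, 3],
                "Y0": 0.0, "Y1": 0.0, "Y2": 0.0,
                "A1": [-1, -1, 1, 1],
                "T1": [0.5, 1.0, 0.25, 1.0],
                "delta": [1, 0, 1, 0],
                "A2R": [1, 0, -1, 0],
                "A2NR": [0, 1, 0, -1],
                "T2": [1.5, 2.0, 1.25, 2.0],
            }
        )
        fit = FakeFit(
            {"beta02": 1.0, "beta12": 0.5, "beta22": 0.3, "beta23": -0.2,
             "beta32": 2.0}
        )
        got = tv.estimated_ai_means(fit, data, design)
        # arm -1: subjects 0 (responder, T2=1.5) and 1 (censored, T2=2.0)
        # AI (-1,+1,+1): mean of [1 -0.5 +0.3 +3.0, 1 -0.5 -0.2 +4.0]
        assert got["(-1,+1,+1)"] == pytest.approx(
            np.mean([1 - 0.5 + 0.3 + 3.0, 1 - 0.5 - 0.2 + 4.0])
        )
        # AI (+1,-1,-1): subjects 2 (responder) and 3 (censored)
        assert got["(+1,-1,-1)"] == pytest.approx(
            np.mean([1 + 0.5 - 0.3 + 2.5, 1 + 0.5 + 0.2 + 4.0])
        )

    def test_plugin_consistent_with_simulated_at_truth(self, table1):
        """Plug-in means at the generating coefficients converge to the
        simulated means as n grows."""
        data = tv.simulate_trial(table1.design, table1.params, 20_000,
                                 tv.replicate_rng(2, 0))
        truth = {k: getattr(table1.params, k) for k in
                 ("beta02", "beta12", "beta22", "beta23", "beta32")}
        est = tv.estimated_ai_means(FakeFit(truth), data, table1.design)
        sim = tv.simulated_ai_means(data, table1.design)
        assert np.abs(est - sim).max() < 0.2  # ~3 MC SEs at this n

    def test_tvmem_and_joint_plugins_agree(self, table1_data, table1):
        """Both estimators' fitted values reproduce the per-cell outcome
        means, so their plug-in AI means coincide despite the biased TVMEM
        time coefficient."""
        ft = tv.fit_tvmem(table1_data)
        fj = tv.fit_joint(table1_data)
        a = tv.estimated_ai_means(ft, table1_data, table1.design)
        b = tv.estimated_ai_means(fj, table1_data, table1.design)
        assert np.abs(a - b).max() < 0.05
        # each AI cell holds ~n/4 subjects with outcome SD ~7, so the
        # simulated cell means carry MC error ~0.45; allow 3 of those
        sim = tv.simulated_ai_means(table1_data, table1.design)
        assert np.abs(a - sim).max() < 1.4


class TestRunReplications:
    def test_single_replicate_degenerate_summaries(self, table1):
        s = tv.run_replications(
            table1.design, table1.params, R=1, n=400, estimators=("tvmem",), seed=3
        )
        tab = s.tables["tvmem"]
        err = tab["mean_estimate"] - tab["truth"]
        assert np.allclose(tab["mse"], err**2, rtol=1e-10)
        assert set(tab["coverage"].unique()) <= {0.0, 1.0}

    def test_mse_identity_and_reproducibility(self, table1):
        kw = dict(R=8, n=300, estimators=("tvmem",), seed=4)
        s1 = tv.run_replications(table1.design, table1.params, **kw)
        s2 = tv.run_replications(table1.design, table1.params, **kw)
        pd.testing.assert_frame_equal(s1.tables["tvmem"], s2.tables["tvmem"])
        est = s1.estimates["tvmem"]
        tab = s1.tables["tvmem"]
        for lab in ("beta12", "beta32"):
            e = est[lab].to_numpy()
            mse = tab.loc[lab, "mse"]
            assert mse == pytest.approx(e.var() + (e.mean() - tab.loc[lab, "truth"]) ** 2)

    def test_nonresp_design_drops_unidentified_truth_rows(self):
        cfg = tv.load_scenario("table5")
        s = tv.run_replications(
            cfg.design, cfg.params, R=2, n=400, estimators=("tvmem",), seed=5
        )
        assert "beta22" not in s.tables["tvmem"].index
        assert "beta23" in s.tables["tvmem"].index


class TestTrialCost:
    def test_hand_computed_two_subject_example(self):
        design = DesignSpec(delta_t=1.0)
        data = pd.DataFrame(
            {
                "id": [0, 1],
                "Y0": 0.0, "Y1": 0.0, "Y2": 0.0,
                "A1": [-1, 1],        # A: medication; B: behavioral
                "T1": [0.5, 1.0],
                "delta": [1, 0],
                "A2R": [1, 0],        # A continues M
                "A2NR": [0, -1],      # B augments (M+B)
                "T2": [1.5, 2.0],
            }
        )
        costs = tv.CostSpec(c1=2.0, c2=1.0)
        # A: 2*0.5 + 2*1 = 3 ; B: 1*1 + (2+1)*1 = 4
        assert tv.trial_cost(data, design, costs) == pytest.approx(7.0)
        # standard pricing charges stage 1 at t10 for everyone: A becomes 4
        assert tv.trial_cost(data, design, costs, stage1_at_t10=True) == pytest.approx(8.0)

    def test_zero_prices_cost_nothing(self, small_data, table1):
        assert tv.trial_cost(small_data, table1.design, tv.CostSpec(0.0, 0.0)) == 0.0

    def test_inconsistent_arm_codes_rejected(self, small_data, table1):
        bad = small_data.copy()
        bad.loc[bad["delta"] == 1, "A2NR"] = 1
        with pytest.raises(ValueError):
            tv.trial_cost(bad, table1.design, tv.CostSpec())

    def test_time_varying_never_costlier_than_standard(self, table1):
        tab = tv.cost_replicates(
            table1.design, table1.params, tv.CostSpec(2.0, 1.0), R=5, n=500, seed=6
        )
        assert (tab["cost_time_varying"] < tab["cost_standard"]).all()

    def test_cost_surface_is_linear_superposition(self, table1):
        grid = tv.cost_surface(
            table1.design, table1.params, [1.0, 2.0], [0.5], R=3, n=300, seed=7
        )
        one = grid.set_index(["c1", "c2"])
        # doubling c1 with c2 fixed adds exactly the c1-unit cost again
        u1 = one.loc[(2.0, 0.5)] - one.loc[(1.0, 0.5)]
        direct = tv.cost_surface(
            table1.design, table1.params, [1.0], [0.0], R=3, n=300, seed=7
        ).iloc[0]
        assert u1["mean_cost_time_varying"] == pytest.approx(
            direct["mean_cost_time_varying"]
        )


class TestPower:
    def test_dominant_ai_always_selected(self):
        # effects ten times the noise scale: selection is certain
        p = GenParams(beta23=40.0, beta12=10.0, beta22=10.0, beta32=2.0)
        d = DesignSpec()
        res = tv.power_comparison(
            d, p, R=6, n=400, seed=8, oracle_n=5000,
            estimator_timevarying="tvmem", estimator_standard="tvmem",
        )
        assert res.power["time_varying"] == 1.0
        assert res.power["standard"] == 1.0

    def test_null_effects_select_uniformly(self):
        """With all intervention effects zero every AI is exchangeable and
        the selection rate sits near 1/8."""
        p = GenParams(beta12=0.0, beta22=0.0, beta23=0.0, beta32=0.0)
        d = DesignSpec()
        res = tv.power_comparison(
            d, p, R=48, n=300, seed=9, oracle_n=4000,
            estimator_timevarying="tvmem", estimator_standard="tvmem",
        )
        band = 3 * np.sqrt(0.125 * 0.875 / 48)
        assert abs(res.power["time_varying"] - 0.125) < band + 1e-9
        assert abs(res.power["standard"] - 0.125) < band + 1e-9

    def test_direction_validated(self, table1):
        with pytest.raises(ValueError):
            tv.power_comparison(table1.design, table1.params, R=1, n=100,
                                direction="upwards", seed=0)
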