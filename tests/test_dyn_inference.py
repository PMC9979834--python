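"""Dynamics likelihood, posterior sampling, comparison and visual summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from panelcomp.dyn_inference import (GroupedData, TYPICAL_SCHEDULES,
                                     dyn_log_likelihood, fit_dynamics, hdi_1d,
                                     param_names, posterior_predictive,
                                     psis_loo_compare, removal_diagnostics,
                                     typical_panel_trajectories)
from panelcomp.experiment_data import DynamicsDataset, TreatmentSchedule
from panelcomp.synthetic_data import DesignSpec


def make_dataset(rows, schedules=None):
    obs = pd.DataFrame(rows, columns=["panel", "week", "phase", "aurita",
                                      "bare", "competitors", "depth", "treatment"])
    obs["n"] = obs[["aurita", "bare", "competitors"]].sum(axis=1)
    schedules = schedules or {}
    full = {int(p): schedules.get(int(p), TreatmentSchedule(int(p), ()))
            for p in obs.panel.unique()}
    return DynamicsDataset(obs=obs, schedules=full)


class TestLogLikelihood:
    def test_floor_keeps_impossible_counts_finite(self):
        # week-1 polyp count with a trajectory that has essentially no polyps
        ds = make_dataset([[1, 1, "pre", 5, 85, 10, 1.0, "C"]])
        g = GroupedData.from_dataset(ds)
        theta = np.array([[0.3, 0.5, 0.2, 1e-8, 0.1, 0.2, 0.4, 0.4]])
        ll = dyn_log_likelihood("basic", theta, g)
        assert np.isfinite(ll).all()

    def test_doubling_counts_identity(self):
        """ll(2y) = C(2y) - 2*C(y) + 2*ll(y) at fixed probabilities."""
        row = [1, 4, "pre", 5, 55, 40, 1.0, "C"]
        double = [1, 4, "pre", 10, 110, 80, 1.0, "C"]
        theta = np.array([[0.3, 0.5, 0.2, 0.05, 0.1, 0.2, 0.4, 0.4]])
        ll1 = dyn_log_likelihood("basic", theta, GroupedData.from_dataset(
            make_dataset([row])))[0, 0]
        ll2 = dyn_log_likelihood("basic", theta, GroupedData.from_dataset(
            make_dataset([double])))[0, 0]
        y = np.array([5, 55, 40])
        c1 = gammaln(101) - gammaln(y + 1).sum()
        c2 = gammaln(201) - gammaln(2 * y + 1).sum()
        assert ll2 == pytest.approx(c2 - 2 * c1 + 2 * ll1, rel=1e-10)

    def test_pointwise_sums_to_total(self, dyn_ds, dyn_post):
        g = GroupedData.from_dataset(dyn_ds)
        theta = dyn_post.flat[:5]
        ll = dyn_log_likelihood(dyn_post.variant, theta, g)
        assert ll.shape == (5, g.n_obs)
        total = dyn_log_likelihood(dyn_post.variant, theta, g).sum(axis=1)
        np.testing.assert_allclose(ll.sum(axis=1), total, rtol=1e-12)

    def test_empty_dataset_gives_empty_loglik(self):
        ds = make_dataset([[1, 1, "pre", 0, 100, 0, 1.0, "C"]])
        ds.obs = ds.obs.iloc[:0]
        g = GroupedData.from_dataset(ds)
        assert dyn_log_likelihood("basic", np.zeros((3, 8)), g).shape == (3, 0)


class TestFit:
    def test_seed_reproducibility(self, dyn_ds):
        kw = dict(n_warmup=60, n_steps=40, thin=2)
        a = fit_dynamics("basic", dyn_ds, seed=4, **kw)
        b = fit_dynamics("basic", dyn_ds, seed=4, **kw)
        np.testing.assert_array_equal(a.chain, b.chain)

    def test_prior_only_fit_recovers_prior(self, dyn_ds):
        empty = DynamicsDataset(obs=dyn_ds.obs.iloc[:0], schedules=dyn_ds.schedules)
        post = fit_dynamics("basic", empty, seed=8, n_warmup=800, n_steps=1500,
                            thin=10, init="prior")
        df = post.draws_df()
        # tolerances sized to the ensemble's Monte-Carlo error (ESS ~ 250)
        r = df["r_O"].to_numpy()
        assert abs(r.mean() - 0.5) < 0.09            # uniform(0, 1)
        assert abs(np.quantile(r, 0.25) - 0.25) < 0.09
        mag = df["a0[1m]"].abs().to_numpy()          # half-normal(1)
        assert abs(np.median(mag) - 0.674) < 0.12

    def test_draws_have_model_signs(self, dyn_post):
        df = dyn_post.draws_df()
        assert (df["a2[1m]"] < 0).all() and (df["b2[3m]"] < 0).all()
        assert (df["a0[1m]"] > 0).all()
        assert df.columns.tolist() == param_names("overgrowth")


class TestComparison:
    def test_identical_models_tie(self, dyn_post):
        tab = psis_loo_compare({"m1": dyn_post, "m2": dyn_post})
        assert tab.delta_elpd.abs().max() == 0.0
        assert (tab.se_diff == 0.0).all()

    def test_wrong_variant_scores_worse_on_overgrowth_data(self, dyn_ds, dyn_post):
        other = fit_dynamics("basic", dyn_ds, seed=10, n_warmup=400,
                             n_steps=300, thin=3)
        tab = psis_loo_compare({"overgrowth": dyn_post, "basic": other})
        assert tab.iloc[0]["model"] == "overgrowth"


class TestVisualSummaries:
    def test_typical_trajectories_sawtooth_and_smooth(self, dyn_post):
        out = typical_panel_trajectories(dyn_post, n_draws=40, seed=1)
        assert set(out.treatment) == {"C", "A", "O"}
        comp_o = out[(out.treatment == "O") & (out.category == "competitors")
                     & (out.depth == 1.0)].sort_values("time")
        # drop at the week-2 application: post mean below pre mean
        pre = comp_o[np.isclose(comp_o.time, 2.0)].iloc[0]["mean"]
        post = comp_o[np.isclose(comp_o.time, 2.0)].iloc[1]["mean"]
        assert post < pre
        # control curves are smooth: no duplicated time points
        comp_c = out[(out.treatment == "C") & (out.category == "competitors")
                     & (out.depth == 1.0)]
        assert comp_c.time.is_unique
        assert (out.lower <= out["mean"] + 1e-9).all()
        assert (out["mean"] <= out.upper + 1e-9).all()

    def test_removal_diagnostics_slopes(self, preset, dyn_ds, dyn_post):
        diag = removal_diagnostics(dyn_ds, dyn_post)
        pairs = diag["pairs"]
        targeted = pairs[(pairs.kind == "O") & pairs.targeted]
        # regression through the origin recovers the generating r_O = 0.5
        slope = (targeted.pre * targeted.post).sum() / (targeted.pre ** 2).sum()
        assert slope == pytest.approx(0.5, abs=0.05)
        # untargeted competitor pairs under A applications lie on slope one
        untgt = pairs[(pairs.kind == "A") & ~pairs.targeted]
        slope1 = (untgt.pre * untgt.post).sum() / (untgt.pre ** 2).sum()
        assert slope1 == pytest.approx(1.0, abs=0.05)
        srow = diag["slopes"].set_index("kind").loc["O"]
        assert srow.lower <= 1 - 0.5 <= srow.upper or abs(srow.slope_mean - 0.5) < 0.1

    def test_no_applications_empty_pairs(self, dyn_ds):
        controls = {p: s for p, s in dyn_ds.schedules.items() if not s.events}
        sub = DynamicsDataset(
            obs=dyn_ds.obs[dyn_ds.obs.panel.isin(controls)].reset_index(drop=True),
            schedules=controls)
        diag = removal_diagnostics(sub)
        assert diag["pairs"].empty

    def test_posterior_predictive_shapes(self, dyn_post):
        out = posterior_predictive(dyn_post, DesignSpec(n_blocks=1), seed=0, n_rep=3)
        assert set(out.rep) == {0, 1, 2}
        assert (out.n == 100).all()
        empty = posterior_predictive(dyn_post, DesignSpec(n_blocks=0), seed=0, n_rep=2)
        assert len(empty) == 0

    def test_predictive_means_match_typical_trajectories(self, dyn_post):
        """Predictive cover frequencies agree with the model curves within
        Monte-Carlo error."""
        sim = posterior_predictive(dyn_post, DesignSpec(n_blocks=2), seed=3, n_rep=40)
        curves = typical_panel_trajectories(dyn_post, n_draws=200, seed=3)
        sel = sim[(sim.treatment == "C") & (sim.week == 8) & (sim.depth == 1.0)
                  & (sim.phase == "pre")]
        emp = sel.competitors.mean() / 100
        cur = curves[(curves.treatment == "C") & (curves.depth == 1.0)
                     & (curves.category == "competitors")
                     & np.isclose(curves.time, 8.0)].iloc[0]["mean"]
        assert emp == pytest.approx(cur, abs=0.08)


def test_hdi_1d_matches_quantiles_for_symmetric_sample(rng):
    x = rng.standard_normal(200000)
    lo, hi = hdi_1d(x, 0.95)
    assert lo == pytest.approx(-1.96, abs=0.05)
    assert hi == pytest.approx(1.96, abs=0.05)


def test_typical_schedules_match_design_defaults():
    d = DesignSpec()
    assert TYPICAL_SCHEDULES["A"][0][0] == d.a_start_week
    assert TYPICAL_SCHEDULES["O"][0][0] == d.o_start_week
    assert TYPICAL_SCHEDULES["C"] == ()
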