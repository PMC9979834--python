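"""Hierarchical compositional MANOVA: likelihood, sampler, summaries, LOCO."""

import numpy as np
import pytest
from scipy.special import gammaln

from panelcomp import comp_manova as cm
from panelcomp.compositions import default_basis
from panelcomp.experiment_data import ManovaDataset
from panelcomp.synthetic_data import (DesignSpec, generate_manova_dataset,
                                      manova_preset_from_cells)


def flat_dataset(counts_rows, treatments, depths, blocks):
    counts = np.asarray(counts_rows, dtype=int)
    return ManovaDataset(counts=counts, totals=counts.sum(axis=1),
                         part_names=("aurita_panel", "bare", "botrylloides",
                                     "bugula", "molgula"),
                         panel=np.arange(1, counts.shape[0] + 1),
                         depth=np.asarray(depths, dtype=float),
                         treatment=np.asarray(treatments, dtype=str),
                         block=np.asarray(blocks, dtype=int))


def zero_params(n_blocks, n_panels):
    return cm.ManovaParams(mu=np.zeros(4), alpha=np.zeros((2, 4)),
                           beta=np.zeros((3, 4)), gamma=np.zeros((2, 3, 4)),
                           delta=np.zeros((n_blocks, 4)),
                           epsilon=np.zeros((n_panels, 4)),
                           Z=np.eye(4), Sigma=np.eye(4))


class TestLogLikelihood:
    def test_uniform_matches_brute_force(self):
        data = flat_dataset([[20] * 5], ["C"], [1.0], [1])
        got = cm.log_likelihood(zero_params(1, 1), data)
        # independent oracle: log(100!) - 5*log(20!) + 100*log(1/5)
        expect = (gammaln(101) - 5 * gammaln(21) + 100 * np.log(0.2))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_empty_observation_contributes_zero(self):
        data = flat_dataset([[0] * 5], ["C"], [1.0], [1])
        assert cm.log_likelihood(zero_params(1, 1), data) == 0.0

    def test_mu_delta_translation_changes_constrained_likelihood(self):
        """With sum-to-zero coding there is no residual translation
        invariance between mu and non-centered block effects unless delta
        absorbs the shift exactly."""
        data = flat_dataset([[30, 30, 20, 10, 10], [10, 20, 30, 20, 20]],
                            ["C", "A"], [1.0, 1.0], [1, 2])
        p = zero_params(2, 2)
        base = cm.log_likelihood(p, data)
        p.mu = p.mu + np.array([0.5, 0, 0, 0])
        shifted = cm.log_likelihood(p, data)
        assert shifted != pytest.approx(base)
        p.delta = p.delta - np.array([0.5, 0, 0, 0])
        restored = cm.log_likelihood(p, data)
        assert restored == pytest.approx(base)


class TestFit:
    def test_seed_determinism(self, manova_data):
        data, _ = manova_data
        kw = dict(n_chains=1, n_warmup=150, n_draws=40, check_diagnostics=False)
        a = cm.fit(data, "no_interaction", seed=7, **kw)
        b = cm.fit(data, "no_interaction", seed=7, **kw)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])

    def test_identical_panels_give_null_treatment_effect(self):
        counts = np.tile([10, 40, 20, 15, 15], (18, 1))
        data = flat_dataset(counts,
                            ["C", "A", "O"] * 6,
                            [1.0, 1.0, 1.0, 3.0, 3.0, 3.0] * 3,
                            sum([[b] * 6 for b in (1, 2, 3)], []))
        post = cm.fit(data, "no_interaction", seed=3, n_chains=1,
                      n_warmup=500, n_draws=300, check_diagnostics=False)
        b = post.stacked("b")
        assert np.abs(b.mean(axis=(0, 1))).max() < 0.15

    def test_unknown_variant_rejected(self):
        with pytest.raises(cm.ManovaError):
            cm.ManovaVariant("anova")


class TestSummaries:
    def test_treatment_composition_shapes_and_normalization(self, manova_post):
        rho = cm.treatment_composition(manova_post, 1.0, "O")
        assert rho.shape[1] == 5
        np.testing.assert_allclose(rho.sum(axis=1), 1.0, atol=1e-12)
        with pytest.raises(cm.ManovaError):
            cm.treatment_composition(manova_post, 2.0, "O")

    def test_no_interaction_perturbation_identity(self, manova_post):
        """rho(j,k) = mu' + alpha_j' + beta_k' composes by perturbation."""
        fx = manova_post.expand_fixed()
        basis = manova_post.basis
        rho = cm.treatment_composition(manova_post, 3.0, "A")
        i = 11
        pieces = [np.exp(z @ basis.matrix) for z in
                  (fx["mu"][i], fx["alpha"][i][1], fx["beta"][i][1])]
        prod = pieces[0] * pieces[1] * pieces[2]
        np.testing.assert_allclose(rho[i], prod / prod.sum(), rtol=1e-10)

    def test_identical_treatment_contrast_is_zero(self, manova_post):
        d = cm.logit_contrast(manova_post, "aurita", ("C", "C"), 1.0)
        assert np.abs(d).max() == 0.0

    def test_contrast_recovers_generating_effect(self, manova_data, manova_post):
        _, truth = manova_data
        from panelcomp.compositions import ilr_inv
        basis = default_basis()

        def true_contrast(part, pair, depth):
            j = (1.0, 3.0).index(depth)
            vals = []
            for t in pair:
                k = ("C", "A", "O").index(t)
                rho = np.asarray(ilr_inv(truth["mu"] + truth["alpha"][j]
                                         + truth["beta"][k], basis))
                share = rho[0] if part == "aurita" else rho[2:5].sum()
                vals.append(np.log(share / (1 - share)))
            return vals[0] - vals[1]

        for part, pair in (("aurita", ("O", "C")), ("competitors", ("A", "C"))):
            for depth in (1.0, 3.0):
                draw = cm.logit_contrast(manova_post, part, pair, depth)
                lo, hi = np.quantile(draw, [0.005, 0.995])
                assert lo <= true_contrast(part, pair, depth) <= hi

    def test_effect_ternaries_uniform_case(self, manova_post):
        amal, sub = cm.effect_ternaries(manova_post, 1.0, "C")
        np.testing.assert_allclose(amal.sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(sub.sum(axis=1), 1.0, atol=1e-12)


class TestHpdRegion:
    def test_contained_fraction_calibrated(self, rng):
        z = rng.standard_normal((10000, 2)) * 0.4
        from panelcomp.compositions import ternary_basis
        tb = ternary_basis()
        samples = np.exp(z @ tb.matrix)
        samples /= samples.sum(axis=1, keepdims=True)
        reg = cm.hpd_region_2d(samples, level=0.95)
        assert 0.93 <= reg.contained_fraction <= 0.97
        assert len(reg.ilr_boundary) >= 1 and not reg.degenerate

    def test_isotropic_region_nearly_circular(self, rng):
        z = rng.standard_normal((8000, 2)) * 0.3
        from panelcomp.compositions import ternary_basis
        tb = ternary_basis()
        samples = np.exp(z @ tb.matrix)
        samples /= samples.sum(axis=1, keepdims=True)
        reg = cm.hpd_region_2d(samples, level=0.95)
        b = np.vstack(reg.ilr_boundary)
        r = np.hypot(b[:, 0] - z[:, 0].mean(), b[:, 1] - z[:, 1].mean())
        assert r.std() / r.mean() < 0.1

    def test_scaling_equivariance(self, rng):
        from panelcomp.compositions import ternary_basis
        tb = ternary_basis()
        z = rng.standard_normal((6000, 2)) * 0.2
        regions = []
        for scale in (1.0, 2.0):
            s = np.exp(scale * z @ tb.matrix)
            s /= s.sum(axis=1, keepdims=True)
            regions.append(cm.hpd_region_2d(s, level=0.95))
        r1 = np.hypot(*np.vstack(regions[0].ilr_boundary).T).mean()
        r2 = np.hypot(*np.vstack(regions[1].ilr_boundary).T).mean()
        assert r2 / r1 == pytest.approx(2.0, rel=0.1)

    def test_degenerate_samples_flagged(self):
        samples = np.tile([0.2, 0.3, 0.5], (2000, 1))
        reg = cm.hpd_region_2d(samples)
        assert reg.degenerate


class TestLoco:
    def test_zero_covariance_limit_equals_conditional(self, manova_post, rng):
        """With Z = Sigma -> 0 the marginal predictive equals the likelihood
        at zero random effects."""
        data = flat_dataset([[20, 30, 20, 15, 15], [25, 25, 20, 15, 15]],
                            ["C", "A"], [1.0, 3.0], [1, 1])
        post = manova_post
        tiny = 1e-20 * np.eye(4)
        draws = {k: v.copy() for k, v in post.draws.items()}
        draws["Z"] = np.broadcast_to(tiny, draws["Z"].shape).copy()
        draws["Sigma"] = np.broadcast_to(tiny, draws["Sigma"].shape).copy()
        post2 = cm.PosteriorDraws(variant=post.variant, basis=post.basis,
                                  design=post.design, draws=draws)
        lpd, _ = cm._block_log_predictive(post2, data, n_re=3,
                                          rng=np.random.default_rng(0))
        # oracle: log mean over draws of the conditional likelihood
        fx = post2.expand_fixed()
        design = cm.Design.from_dataset(data)
        S = fx["mu"].shape[0]
        take = np.linspace(0, S - 1, min(400, S)).astype(int)
        eta = (fx["mu"][take][:, None] + fx["alpha"][take][:, design.j]
               + fx["beta"][take][:, design.k] + fx["gamma"][take][:, design.j, design.k])
        ll = cm._multinomial_logpmf(data.counts.astype(float),
                                    cm._log_rho(eta, post.basis)).sum(axis=1)
        from scipy.special import logsumexp
        expect = logsumexp(ll) - np.log(ll.size)
        assert lpd == pytest.approx(expect, abs=1e-6)

    def test_identical_variants_tie(self, preset):
        data, _ = generate_manova_dataset(preset, DesignSpec(n_blocks=3), seed=13)
        kw = dict(n_chains=1, n_warmup=300, n_draws=150)
        tab = cm.loco_cv(data, variants=("no_interaction", "no_interaction"),
                         seed=2, n_re=30, fit_kwargs=kw)
        assert tab.delta_elpd.abs().max() == 0.0
        assert (tab.se_diff == 0.0).all()

    def test_requires_three_blocks(self, preset):
        data, _ = generate_manova_dataset(preset, DesignSpec(n_blocks=2), seed=1)
        with pytest.raises(cm.ManovaError):
            cm.loco_cv(data, seed=0)
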