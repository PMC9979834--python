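# panelcomp

Composition and competition analyses for settlement-panel removal
experiments on fouling communities containing jellyfish polyps.

Sessile marine communities on hard substrate are a canonical example of
competition for space, and the sessile polyp stage of jellyfish such as
*Aurelia aurita* is an under-studied member of them. A standard way to
probe these interactions is a press experiment: settlement panels in a
randomized block design at two depths, with weekly removal of half the
polyps (treatment A) or half the other sessile organisms (treatment O),
and weekly 100-point photographic cover counts. `panelcomp` provides a
tested, reusable pipeline for the two analyses such an experiment needs,
plus a synthetic-data generator that reproduces the full design so every
stage is testable without field data.

**Track 1 — final composition.** Percent cover is compositional, so the
community at the end of the experiment is analyzed on the simplex. For the
panel at depth *j*, treatment *k*, block *l*:

    y_jkl ~ multinomial(n_jkl, ρ_jkl)
    ρ_jkl = ilr⁻¹(μ + α_j + β_k + γ_jk + δ_l + ε_jkl),   δ_l ~ N(0, Z),  ε_jkl ~ N(0, Σ)

a Bayesian latent hierarchical compositional MANOVA in isometric
logratio coordinates, fitted by a blocked adaptive
Metropolis-within-Gibbs sampler with conjugate inverse-Wishart updates
for Z and Σ and exact interweaving moves for the fixed/latent trade-off.
Treatment effects are read off as logit-scale contrasts (e.g.
logit(*A. aurita* share) under O minus under C) and as orthogonal ternary
projections; model variants (with/without depth, treatment, interaction)
are compared by leave-one-block-out cross-validation with random effects
integrated out.

**Track 2 — community dynamics.** Five ODE models of preemptive
competition for space between potential competitors (cover x) and polyps
(density y₁, area per polyp δ):

    dx/dt  = a₀(1 − x − δy₁) + a₁x(1 − x − δy₁) + a₂x
    dy₁/dt = b₀(1 − x − δy₁) + b₁y₁(1 − x − δy₁) + b₂y₁

extended one parameter at a time by settlement facilitation, growth
facilitation, overgrowth of polyps by competitors, or protection from
predators, with weekly removals as instantaneous proportional reductions
(estimated fractions r_A, r_O). Models are fitted to the weekly
three-category counts by ensemble MCMC (emcee), compared by PSIS-LOO, and
interrogated through the community matrix — the partial derivatives of
proportional growth rates with respect to relative abundances — whose
(1,2) entry maps where polyps help or hurt their competitors.

## Worked example

Generate a synthetic experiment at the study design (60 panels, 8 weeks,
overgrowth dynamics, removal targets 0.5) and run both tracks:

```python
import numpy as np
from panelcomp import comp_manova
from panelcomp.dyn_inference import fit_dynamics
from panelcomp.env_intervals import summarize_environment
from panelcomp.experiment_data import dynamics_dataset, manova_subset
from panelcomp.synthetic_data import DesignSpec, generate_dynamics_experiment, load_preset

preset = load_preset()
table, truth = generate_dynamics_experiment("overgrowth", preset, DesignSpec(), seed=0)

print(summarize_environment(table.env).round(3).to_string(index=False))

data = manova_subset(table)
post = comp_manova.fit(data, "no_interaction", seed=0, n_chains=2,
                       n_warmup=1000, n_draws=500, check_diagnostics=False)
d = comp_manova.logit_contrast(post, "aurita", ("O", "C"), 1.0)
lo, hi = np.quantile(d, [0.025, 0.975])
print(f"logit(A. aurita) O vs C at 1 m: {d.mean():.2f} (95% CI {lo:.2f}, {hi:.2f})")

dyn = fit_dynamics("overgrowth", dynamics_dataset(table), seed=0,
                   n_warmup=600, n_steps=500, thin=3)
df = dyn.draws_df()
print(f"removal fractions: r_A = {df['r_A'].mean():.2f}, r_O = {df['r_O'].mean():.2f}")
```

Output:

```
        variable  n_pairs  mean_difference  lower  upper  level
dissolved_oxygen        8           -0.498 -1.382  0.387   0.95
     temperature        8           -0.328 -0.554 -0.101   0.95
        salinity        7            0.131 -0.009  0.272   0.95
logit(A. aurita) O vs C at 1 m: 2.85 (95% CI 2.28, 3.51)
removal fractions: r_A = 0.49, r_O = 0.51
```

The environmental table gives one-sample t-based 95% credible intervals
for the weekly 3 m − 1 m differences (water is slightly colder at depth;
salinity has 7 pairs because week 5 is unmeasured). The logit contrast
says removing competitors raises the odds of a point landing on
*A. aurita* by a factor e^2.85 ≈ 17 at 1 m in this simulation — the
generating effect is inside the interval. The dynamics fit recovers the
removal fractions used by the generator (0.5) from the post- versus
pre-treatment cover drops.

A command-line interface wraps the same steps
(`panelcomp simulate | validate | env-intervals | fit-manova |
fit-dynamics | compare-dynamics | report`); `panelcomp report --config
cfg.yaml` runs the full pipeline into a directory with a MANIFEST of
completed stages.

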