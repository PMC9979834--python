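"""Synthetic experiments with the structure both analyses assume.

The generator reproduces the study design — 10 blocks of 6 panels, two
depths, three removal treatments, 8 weekly 100-point photographs with pre-
and post-treatment phases — and the two generative processes the pipeline
fits: deterministic competition-for-space trajectories with multinomial
point counts, and the hierarchical compositional MANOVA.  Truth is retained
for recovery tests.  Scenario presets live in a versioned JSON config
(``presets/default.json``); the default emulates the study's qualitative
pattern (more competitor cover at 1 m, more polyps and bare space at 3 m,
low polyp cover overall).

Not emulated: photograph noise, taxon misidentification, spatial point
placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from . import compositions as comp
from .dynamics import DynParams, integrate_batch, params_to_rel
from .experiment_data import (CATEGORIES, ExperimentTable, ManovaDataset,
                              validate)

COMPETITOR_TAXA = ("botrylloides", "bugula", "molgula", "ascidiella",
                   "botryllus", "other")


@dataclass(frozen=True)
class DesignSpec:
    """Experimental design; defaults reproduce the 60-panel study layout."""

    n_blocks: int = 10
    depths: tuple[float, ...] = (1.0, 3.0)
    treatments: tuple[str, ...] = ("C", "A", "O")
    n_weeks: int = 8
    points_per_photo: int = 100
    a_start_week: int = 3
    o_start_week: int = 2
    mistaken: tuple[int, int] | None = None   # (panel_id, week): A applied to a C panel

    @property
    def n_panels(self) -> int:
        return self.n_blocks * len(self.depths) * len(self.treatments)

    def panels(self) -> pd.DataFrame:
        rows = []
        pid = 0
        for b in range(1, self.n_blocks + 1):
            for d in self.depths:
                for t in self.treatments:
                    pid += 1
                    rows.append({"panel": pid, "block": b, "depth": d,
                                 "treatment": t, "mistaken_week": ""})
        meta = pd.DataFrame(rows)
        if self.mistaken is not None:
            pid, week = self.mistaken
            row = meta["panel"] == pid
            if not row.any() or meta.loc[row, "treatment"].iloc[0] != "C":
                raise ValueError("mistaken panel must be an existing control panel")
            meta.loc[row, "mistaken_week"] = week
        return meta

    def schedule(self) -> pd.DataFrame:
        meta = self.panels()
        rows = []
        for _, m in meta.iterrows():
            if m["treatment"] == "A":
                rows += [{"panel": m["panel"], "week": w, "kind": "A"}
                         for w in range(self.a_start_week, self.n_weeks + 1)]
            elif m["treatment"] == "O":
                rows += [{"panel": m["panel"], "week": w, "kind": "O"}
                         for w in range(self.o_start_week, self.n_weeks + 1)]
            elif m["mistaken_week"] != "":
                rows.append({"panel": m["panel"], "week": int(m["mistaken_week"]),
                             "kind": "A"})
        return pd.DataFrame(rows, columns=["panel", "week", "kind"])


@dataclass
class ManovaEffectPreset:
    """Expanded sum-to-zero fixed effects in ilr space plus covariances."""

    mu: np.ndarray                # (4,)
    alpha: np.ndarray             # (n_depths, 4)
    beta: np.ndarray              # (n_treatments, 4)
    gamma: np.ndarray             # (n_depths, n_treatments, 4)
    Z: np.ndarray                 # (4, 4)
    Sigma: np.ndarray             # (4, 4)


@dataclass
class ScenarioPreset:
    """Named generating parameters for both synthetic tracks."""

    variant: str
    dyn_params: dict[float, DynParams]       # per depth, natural units
    manova: ManovaEffectPreset
    competitor_split_alpha: np.ndarray = field(
        default_factory=lambda: np.array([4.0, 4.0, 6.0, 0.5, 0.5, 0.3]))


def manova_preset_from_cells(cells: dict[tuple[float, str], np.ndarray],
                             Z_scale: float, Sigma_scale: float,
                             depths=(1.0, 3.0),
                             treatments=("C", "A", "O")) -> ManovaEffectPreset:
    """Derive sum-to-zero effects from target cell compositions.

    Cell ilr means are decomposed exactly into mu + alpha + beta + gamma by
    averaging, so the preset reproduces the requested compositions when all
    random effects are zero.
    """
    basis = comp.default_basis()
    eta = np.array([[comp.ilr(comp.close(np.asarray(cells[(d, t)])), basis)
                     for t in treatments] for d in depths])  # (nj, nk, 4)
    mu = eta.mean(axis=(0, 1))
    alpha = eta.mean(axis=1) - mu
    beta = eta.mean(axis=0) - mu
    gamma = eta - mu - alpha[:, None, :] - beta[None, :, :]
    return ManovaEffectPreset(mu=mu, alpha=alpha, beta=beta, gamma=gamma,
                              Z=Z_scale * np.eye(4), Sigma=Sigma_scale * np.eye(4))


def load_preset(name: str = "default") -> ScenarioPreset:
    """Load a scenario preset from the versioned JSON config."""
    text = resources.files("panelcomp.presets").joinpath(f"{name}.json").read_text()
    cfg = json.loads(text)
    dyn = cfg["dynamics"]
    params = {}
    for dkey, p in dyn["depths"].items():
        params[float(dkey)] = DynParams(r_A=dyn["r_A"], r_O=dyn["r_O"], **p)
    cells = {}
    for key, val in cfg["manova"]["cells"].items():
        d, t = key.split(",")
        cells[(float(d), t)] = np.array(val)
    manova = manova_preset_from_cells(cells, cfg["manova"]["Z_scale"],
                                      cfg["manova"]["Sigma_scale"])
    return ScenarioPreset(variant=dyn["variant"], dyn_params=params, manova=manova,
                          competitor_split_alpha=np.array(cfg["competitor_split_alpha"]))


def _env_table(design: DesignSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Weekly paired environmental records emulating the study's measurements.

    Dissolved oxygen ~8 mg/L, slightly lower at 3 m; temperature ~18 C,
    slightly colder at 3 m; salinity ~15 psu, missing in week 5 at both
    depths as in the study."""
    rows = []
    for week in range(1, design.n_weeks + 1):
        for depth in design.depths:
            deep = depth == max(design.depths)
            rows.append({
                "week": week, "depth": depth,
                "dissolved_oxygen": round(8.0 - 0.4 * deep + 0.5 * rng.standard_normal(), 2),
                "temperature": round(18.0 - 0.26 * deep - 0.3 * week / 8
                                     + 0.15 * rng.standard_normal(), 2),
                "salinity": (np.nan if week == 5
                             else round(15.0 + 0.05 * deep + 0.1 * rng.standard_normal(), 2)),
            })
    return pd.DataFrame(rows)


def simulate_dynamics_counts(variant: str, rel_by_depth: dict[float, dict],
                             design: DesignSpec,
                             rng: np.random.Generator,
                             split_alpha: np.ndarray | None = None) -> pd.DataFrame:
    """Three-category counts along deterministic trajectories (tidy frame).

    Used both by the full generator and by posterior predictive simulation;
    ``rel_by_depth`` maps depth to scalar rel-parameter dicts.
    """
    meta = design.panels()
    sched = design.schedule()
    rows = []
    for _, m in meta.iterrows():
        events = tuple((int(r["week"]), r["kind"])
                       for _, r in sched[sched["panel"] == m["panel"]].iterrows())
        rel = rel_by_depth[m["depth"]]
        u_pre, u_post = integrate_batch(variant, rel, events, design.n_weeks)
        applied = {w for w, _k in events}
        for week in range(1, design.n_weeks + 1):
            pre = u_pre[week - 1]
            p_pre = np.clip([pre[1], 1 - pre[0] - pre[1], pre[0]], 0, None)
            y = rng.multinomial(design.points_per_photo, p_pre / p_pre.sum())
            rows.append({"panel": m["panel"], "week": week, "phase": "pre",
                         "aurita": y[0], "bare": y[1], "competitors": y[2],
                         "n": y.sum(), "depth": m["depth"], "treatment": m["treatment"]})
            if week in applied:
                post = u_post[week - 1]
                p_post = np.clip([post[1], 1 - post[0] - post[1], post[0]], 0, None)
                y = rng.multinomial(design.points_per_photo, p_post / p_post.sum())
            rows.append({"panel": m["panel"], "week": week, "phase": "post",
                         "aurita": y[0], "bare": y[1], "competitors": y[2],
                         "n": y.sum(), "depth": m["depth"], "treatment": m["treatment"]})
    return pd.DataFrame(rows)


def generate_dynamics_experiment(variant: str, preset: ScenarioPreset,
                                 design: DesignSpec | None = None,
                                 seed: int = 0) -> tuple[ExperimentTable, dict]:
    """Full synthetic experiment table plus retained truth.

    Counts for all nine categories: the competitor total is split among the
    named taxa and 'other' with a per-panel Dirichlet weight vector (fixed
    across weeks), exercising the MANOVA taxon-inclusion rule; polyps on
    competitors are kept at zero, matching their negligible role.
    """
    design = design or DesignSpec()
    rng = np.random.default_rng(seed)
    rel_by_depth = {}
    for d, p in preset.dyn_params.items():
        rel = params_to_rel(variant, p)
        rel_by_depth[d] = {k: getattr(rel, k)
                           for k in ("a0", "a1", "a2", "db0", "b1", "b2",
                                     "extra", "r_A", "r_O")}

    three = simulate_dynamics_counts(variant, rel_by_depth, design, rng,
                                     preset.competitor_split_alpha)
    meta = design.panels()
    split_w = {int(p): rng.dirichlet(preset.competitor_split_alpha)
               for p in meta["panel"]}

    rows = []
    for _, r in three.iterrows():
        base = {"panel": int(r["panel"]), "week": int(r["week"]), "phase": r["phase"]}
        counts = {c: 0 for c in CATEGORIES}
        counts["aurita_panel"] = int(r["aurita"])
        counts["bare"] = int(r["bare"])
        if r["competitors"] > 0:
            split = rng.multinomial(int(r["competitors"]), split_w[int(r["panel"])])
            # 'other' stays a rare catch-all (<= 7 points, as on real panels)
            if split[-1] > 7:
                split[np.argmax(split[:-1])] += split[-1] - 7
                split[-1] = 7
            for taxon, v in zip(COMPETITOR_TAXA, split):
                counts[taxon] = int(v)
        for cat, v in counts.items():
            rows.append({**base, "category": cat, "count": v,
                         "n": design.points_per_photo})
    counts_df = pd.DataFrame(rows)

    # re-impose post == pre (same photo reused) where no application happened
    sched = design.schedule()
    applied = set(map(tuple, sched[["panel", "week"]].itertuples(index=False)))
    piv = counts_df.pivot_table(index=["panel", "week", "category"], columns="phase",
                                values="count", aggfunc="first").reset_index()
    no_app = ~piv.apply(lambda r: (r["panel"], r["week"]) in applied, axis=1)
    piv.loc[no_app, "post"] = piv.loc[no_app, "pre"]
    counts_df = piv.melt(id_vars=["panel", "week", "category"],
                         value_vars=["pre", "post"], var_name="phase",
                         value_name="count")
    counts_df["count"] = counts_df["count"].astype(int)
    counts_df["n"] = design.points_per_photo

    table = validate(counts_df, meta, _env_table(design, rng), sched)
    truth = {"params": _truth_params(variant, rel_by_depth, design),
             "rel_by_depth": rel_by_depth, "three_category": three}
    return table, truth


def _truth_params(variant: str, rel_by_depth: dict[float, dict],
                  design: DesignSpec) -> dict[str, float]:
    from .dyn_inference import param_names
    from .dynamics import EXTRA_PARAM

    out = {}
    depths = tuple(sorted(rel_by_depth))
    for name in param_names(variant, depths):
        if name == "r_A":
            out[name] = float(rel_by_depth[depths[0]]["r_A"])
        elif name == "r_O":
            out[name] = float(rel_by_depth[depths[0]]["r_O"])
        else:
            p, d = name[:-1].split("[")
            key = "extra" if p == EXTRA_PARAM[variant] else p
            out[name] = float(rel_by_depth[float(d[:-1])][key])
    return out


def generate_manova_dataset(preset: ScenarioPreset | ManovaEffectPreset,
                            design: DesignSpec | None = None,
                            seed: int = 0) -> tuple[ManovaDataset, dict]:
    """Five-part counts per panel drawn from the hierarchical MANOVA model."""
    design = design or DesignSpec()
    eff = preset.manova if isinstance(preset, ScenarioPreset) else preset
    rng = np.random.default_rng(seed)
    basis = comp.default_basis()
    meta = design.panels()

    depths = tuple(sorted(design.depths))
    treatments = design.treatments
    delta = rng.multivariate_normal(np.zeros(4), eff.Z, size=design.n_blocks,
                                    method="eigh")
    n = len(meta)
    eps = rng.multivariate_normal(np.zeros(4), eff.Sigma, size=n, method="eigh")

    counts = np.empty((n, 5), dtype=int)
    for i, (_, m) in enumerate(meta.iterrows()):
        j = depths.index(m["depth"])
        k = treatments.index(m["treatment"])
        eta = (eff.mu + eff.alpha[j] + eff.beta[k] + eff.gamma[j, k]
               + delta[int(m["block"]) - 1] + eps[i])
        rho = np.asarray(comp.ilr_inv(eta, basis))
        counts[i] = rng.multinomial(design.points_per_photo, rho)

    ds = ManovaDataset(
        counts=counts, totals=counts.sum(axis=1),
        part_names=("aurita_panel", "bare", "botrylloides", "bugula", "molgula"),
        panel=meta["panel"].to_numpy(), depth=meta["depth"].to_numpy(dtype=float),
        treatment=meta["treatment"].to_numpy(dtype=str),
        block=meta["block"].to_numpy(dtype=int))
    truth = {"mu": eff.mu, "alpha": eff.alpha, "beta": eff.beta,
             "gamma": eff.gamma, "Z": eff.Z, "Sigma": eff.Sigma,
             "delta": delta, "epsilon": eps}
    return ds, truth
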