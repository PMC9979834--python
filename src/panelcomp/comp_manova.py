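"""Bayesian latent hierarchical compositional MANOVA for final cover.

Observation model, for the panel from depth j, treatment k, block l:

    y_jkl   ~ multinomial(n_jkl, rho_jkl)
    rho_jkl = ilr^{-1}(mu + alpha_j + beta_k + gamma_jk + delta_l + eps_jkl)
    delta_l ~ N(0, Z),   eps_jkl ~ N(0, Sigma)

with sum-to-zero effect coding for depth (alpha), treatment (beta) and
their doubly centered interaction (gamma) in 4-dimensional ilr space.
Model variants drop the interaction, the treatment effect, or the depth
effect.

Inference is a blocked adaptive Metropolis-within-Gibbs sampler: Gaussian
random-walk updates (scales tuned during warmup only) for the fixed
effects and the conditionally independent block/panel effects, and exact
conjugate inverse-Wishart Gibbs draws for Z and Sigma given the latent
effects.  Convergence is summarized with rank-normalized R-hat and bulk
ESS via arviz.

Weakly informative priors: N(0, 2.5^2) per component on fixed effects in
ilr space; inverse-Wishart(d + 2, 0.5 I) on Z and Sigma.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .compositions import (ContrastMatrix, balance_basis, default_basis,
                           ternary_basis, ilr)
from .experiment_data import ManovaDataset


def _pivot_basis(D: int) -> ContrastMatrix:
    """Pivot-balance basis for a D-part composition (used when the
    taxon-inclusion rule yields more than the usual five parts)."""
    return balance_basis([(tuple(range(i + 1)), (i + 1,)) for i in range(D - 1)], D)

VARIANT_NAMES = ("full", "no_interaction", "no_treatment", "no_depth")

PRIOR_FIXED_SD = 2.5
PRIOR_IW_DF_EXTRA = 2      # nu0 = d + PRIOR_IW_DF_EXTRA
PRIOR_IW_SCALE = 0.5       # S0 = PRIOR_IW_SCALE * I


class ManovaError(ValueError):
    pass


@dataclass(frozen=True)
class ManovaVariant:
    """Which fixed effects enter the linear predictor."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in VARIANT_NAMES:
            raise ManovaError(f"unknown variant {self.name!r}")

    @property
    def depth(self) -> bool:
        return self.name != "no_depth"

    @property
    def treatment(self) -> bool:
        return self.name != "no_treatment"

    @property
    def interaction(self) -> bool:
        return self.name == "full"


@dataclass
class ManovaParams:
    """One full parameter set (expanded, sum-to-zero arrays)."""

    mu: np.ndarray                 # (4,)
    alpha: np.ndarray              # (n_depths, 4), rows sum to zero
    beta: np.ndarray               # (n_treatments, 4), rows sum to zero
    gamma: np.ndarray              # (n_depths, n_treatments, 4), doubly centered
    delta: np.ndarray              # (n_blocks, 4)
    epsilon: np.ndarray            # (n_panels, 4)
    Z: np.ndarray                  # (4, 4) SPD
    Sigma: np.ndarray              # (4, 4) SPD


@dataclass
class Design:
    """Index arrays mapping panels to design cells."""

    depth_values: np.ndarray       # sorted unique depths
    treatments: tuple[str, ...]    # ("C", "A", "O")
    j: np.ndarray                  # per-panel depth index
    k: np.ndarray                  # per-panel treatment index
    l: np.ndarray                  # per-panel block index
    block_ids: np.ndarray

    @classmethod
    def from_dataset(cls, data: ManovaDataset) -> "Design":
        depth_values = np.unique(data.depth)
        treatments = ("C", "A", "O")
        blocks = np.unique(data.block)
        j = np.searchsorted(depth_values, data.depth)
        k = np.array([treatments.index(t) for t in data.treatment])
        l = np.searchsorted(blocks, data.block)
        return cls(depth_values, treatments, j, k, l, blocks)


def _multinomial_logpmf(counts: np.ndarray, log_rho: np.ndarray) -> np.ndarray:
    """Row-wise multinomial log-pmf; broadcasts over leading axes of log_rho."""
    n = counts.sum(axis=-1)
    const = gammaln(n + 1) - gammaln(counts + 1).sum(axis=-1)
    return const + (counts * log_rho).sum(axis=-1)


def _log_rho(eta: np.ndarray, basis: ContrastMatrix) -> np.ndarray:
    clr = eta @ basis.matrix
    return clr - logsumexp(clr, axis=-1, keepdims=True)


def log_likelihood(params: ManovaParams, data: ManovaDataset,
                   basis: ContrastMatrix | None = None) -> float:
    """Total multinomial log-likelihood of the five-part counts."""
    basis = basis or default_basis()
    design = Design.from_dataset(data)
    eta = (params.mu
           + params.alpha[design.j]
           + params.beta[design.k]
           + params.gamma[design.j, design.k]
           + params.delta[design.l]
           + params.epsilon)
    if not np.all(np.isfinite(eta)):
        raise ManovaError("non-finite linear predictor")
    return float(_multinomial_logpmf(data.counts, _log_rho(eta, basis)).sum())


# ---------------------------------------------------------------------------
# sampler


@dataclass
class PosteriorDraws:
    """Posterior draws (chain-major) plus design metadata and diagnostics."""

    variant: ManovaVariant
    basis: ContrastMatrix
    design: Design
    draws: dict[str, np.ndarray]   # each (n_chains, n_draws, ...)
    diagnostics: pd.DataFrame = field(default=None)

    @property
    def n_draws_total(self) -> int:
        s = self.draws["mu"].shape
        return s[0] * s[1]

    def stacked(self, name: str) -> np.ndarray:
        a = self.draws[name]
        return a.reshape((-1,) + a.shape[2:])

    def expand_fixed(self) -> dict[str, np.ndarray]:
        """Sum-to-zero expanded fixed effects per pooled draw."""
        S = self.n_draws_total
        d = self.basis.D - 1
        nj = len(self.design.depth_values)
        nk = len(self.design.treatments)
        mu = self.stacked("mu")
        alpha = np.zeros((S, nj, d))
        beta = np.zeros((S, nk, d))
        gamma = np.zeros((S, nj, nk, d))
        if self.variant.depth:
            a = self.stacked("a")
            alpha[:, 0] = a
            alpha[:, 1] = -a
        if self.variant.treatment:
            b = self.stacked("b")
            beta[:, 0] = b[:, 0]
            beta[:, 1] = b[:, 1]
            beta[:, 2] = -b[:, 0] - b[:, 1]
        if self.variant.interaction:
            g = self.stacked("g")
            gamma[:, 0, 0] = g[:, 0]
            gamma[:, 0, 1] = g[:, 1]
            gamma[:, 0, 2] = -g[:, 0] - g[:, 1]
            gamma[:, 1] = -gamma[:, 0]
        return {"mu": mu, "alpha": alpha, "beta": beta, "gamma": gamma}


def _free_blocks(variant: ManovaVariant, d: int = 4) -> list[tuple[str, tuple[int, ...]]]:
    blocks = [("mu", (d,))]
    if variant.depth:
        blocks.append(("a", (d,)))
    if variant.treatment:
        blocks.append(("b", (2, d)))
    if variant.interaction:
        blocks.append(("g", (2, d)))
    return blocks


def _panel_eta(state: dict, variant: ManovaVariant, design: Design) -> np.ndarray:
    eta = np.tile(state["mu"], (design.j.size, 1))
    if variant.depth:
        sign = np.where(design.j == 0, 1.0, -1.0)[:, None]
        eta = eta + sign * state["a"]
    if variant.treatment:
        b = state["b"]
        beta = np.vstack([b[0], b[1], -b[0] - b[1]])
        eta = eta + beta[design.k]
    if variant.interaction:
        g = state["g"]
        gam0 = np.vstack([g[0], g[1], -g[0] - g[1]])
        sign = np.where(design.j == 0, 1.0, -1.0)[:, None]
        eta = eta + sign * gam0[design.k]
    return eta + state["delta"][design.l] + state["eps"]


def _panel_loglik(counts: np.ndarray, eta: np.ndarray, basis: ContrastMatrix) -> np.ndarray:
    return (counts * _log_rho(eta, basis)).sum(axis=-1)


def _fixed_effect_coefs(variant: ManovaVariant, design: Design) -> list[tuple[str, int | None, np.ndarray]]:
    """Per-panel coefficients c_i of each free fixed-effect vector in eta."""
    out: list[tuple[str, int | None, np.ndarray]] = [
        ("mu", None, np.ones(design.j.size))]
    sign = np.where(design.j == 0, 1.0, -1.0)
    if variant.depth:
        out.append(("a", None, sign))
    trt = {0: (1.0, 0.0), 1: (0.0, 1.0), 2: (-1.0, -1.0)}  # C, A, O rows of (b0, b1)
    if variant.treatment:
        c = np.array([trt[k] for k in design.k])
        out.append(("b", 0, c[:, 0]))
        out.append(("b", 1, c[:, 1]))
    if variant.interaction:
        c = np.array([trt[k] for k in design.k])
        out.append(("g", 0, sign * c[:, 0]))
        out.append(("g", 1, sign * c[:, 1]))
    return out


def _draw_mvn_from_precision(P: np.ndarray, b: np.ndarray,
                             rng: np.random.Generator) -> np.ndarray:
    """One draw from N(P^{-1} b, P^{-1}) via Cholesky."""
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, b)
    z = rng.standard_normal(b.shape[-1])
    return mean + np.linalg.solve(L.T, z)


def _interweave(state: dict, variant: ManovaVariant, design: Design,
                Z_inv: np.ndarray, Sig_inv: np.ndarray,
                rng: np.random.Generator) -> None:
    """Exact Gibbs moves along likelihood-invariant directions.

    Each free fixed-effect vector theta trades off against the panel
    effects (theta + v, eps_i - c_i v leaves every linear predictor
    unchanged), so v has a Gaussian conditional determined by the priors
    alone; sampling it exactly removes the random-walk funnel between
    fixed and latent effects.  The same applies between block effects and
    their panels' effects, and between mu and the block effects.
    """
    d = state["mu"].size
    Id = np.eye(d)
    tau = 1.0 / PRIOR_FIXED_SD**2

    # block effects vs their panels' effects
    n_per_block = np.bincount(design.l, minlength=state["delta"].shape[0])
    eps_sum = np.zeros_like(state["delta"])
    np.add.at(eps_sum, design.l, state["eps"])
    for l in range(state["delta"].shape[0]):
        P = Z_inv + n_per_block[l] * Sig_inv
        b = Sig_inv @ eps_sum[l] - Z_inv @ state["delta"][l]
        v = _draw_mvn_from_precision(P, b, rng)
        state["delta"][l] += v
        state["eps"][design.l == l] -= v

    # fixed effects vs panel effects
    for name, row, c in _fixed_effect_coefs(variant, design):
        theta = state[name] if row is None else state[name][row]
        P = tau * Id + float(c @ c) * Sig_inv
        b = Sig_inv @ (c @ state["eps"]) - tau * theta
        v = _draw_mvn_from_precision(P, b, rng)
        if row is None:
            state[name] = theta + v
        else:
            state[name][row] = theta + v
        state["eps"] -= c[:, None] * v

    # overall mean vs block effects
    L = state["delta"].shape[0]
    P = tau * Id + L * Z_inv
    b = Z_inv @ state["delta"].sum(axis=0) - tau * state["mu"]
    v = _draw_mvn_from_precision(P, b, rng)
    state["mu"] = state["mu"] + v
    state["delta"] -= v


def fit(data: ManovaDataset, variant: ManovaVariant | str = "no_interaction",
        seed: int = 0, n_chains: int = 4, n_warmup: int = 1500,
        n_draws: int = 1000, thin: int = 1,
        basis: ContrastMatrix | None = None,
        check_diagnostics: bool = True) -> PosteriorDraws:
    """Sample the posterior with blocked adaptive Metropolis-within-Gibbs.

    Reproducible for a given seed; raises no error on poor convergence but
    records rank-normalized R-hat and bulk ESS in ``diagnostics`` and warns
    when R-hat > 1.01 (set ``check_diagnostics=False`` to silence).
    """
    if isinstance(variant, str):
        variant = ManovaVariant(variant)
    D = data.counts.shape[1]
    basis = basis or (default_basis() if D == 5 else _pivot_basis(D))
    if basis.D != D:
        raise ManovaError(f"basis dimension {basis.D} != {D} parts")
    design = Design.from_dataset(data)
    counts = data.counts.astype(float)
    N = data.n_panels
    L = design.block_ids.size
    d = D - 1

    nu0 = d + PRIOR_IW_DF_EXTRA
    S0 = PRIOR_IW_SCALE * np.eye(d)

    blocks = _free_blocks(variant, d)
    keep: dict[str, list] = {name: [] for name, _ in blocks}
    keep.update({"delta": [], "eps": [], "Z": [], "Sigma": []})

    for chain in range(n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([seed, chain]))
        state = {name: 0.1 * rng.standard_normal(shape)
                 for name, shape in blocks}
        state["delta"] = 0.1 * rng.standard_normal((L, d))
        state["eps"] = 0.1 * rng.standard_normal((N, d))
        Z = np.eye(d)
        Sigma = np.eye(d)

        log_scales = {name: np.log(0.1) for name, _ in blocks}
        ls_delta = np.full(L, np.log(0.1))
        ls_eps = np.full(N, np.log(0.1))

        chain_keep = {name: [] for name in keep}
        total = n_warmup + n_draws * thin
        for it in range(total):
            adapt = it < n_warmup
            step = 1.0 / np.sqrt(1 + it) if adapt else 0.0

            # --- fixed-effect blocks (full-likelihood Metropolis)
            for name, shape in blocks:
                cur = state[name]
                eta = _panel_eta(state, variant, design)
                ll_cur = _panel_loglik(counts, eta, basis).sum()
                prop = cur + np.exp(log_scales[name]) * rng.standard_normal(shape)
                state[name] = prop
                ll_prop = _panel_loglik(counts, _panel_eta(state, variant, design),
                                        basis).sum()
                lp = (ll_prop - ll_cur
                      + ((cur**2).sum() - (prop**2).sum()) / (2 * PRIOR_FIXED_SD**2))
                if np.log(rng.uniform()) < lp:
                    acc = 1.0
                else:
                    state[name] = cur
                    acc = 0.0
                if adapt:
                    log_scales[name] += step * (acc - 0.25)

            # --- panel effects: conditionally independent Metropolis
            Sig_inv = np.linalg.inv(Sigma)
            eta_base = _panel_eta(state, variant, design) - state["eps"]
            cur = state["eps"]
            prop = cur + np.exp(ls_eps)[:, None] * rng.standard_normal((N, d))
            ll_cur = _panel_loglik(counts, eta_base + cur, basis)
            ll_prop = _panel_loglik(counts, eta_base + prop, basis)
            pr_cur = -0.5 * np.einsum("nd,de,ne->n", cur, Sig_inv, cur)
            pr_prop = -0.5 * np.einsum("nd,de,ne->n", prop, Sig_inv, prop)
            accept = np.log(rng.uniform(size=N)) < (ll_prop + pr_prop - ll_cur - pr_cur)
            state["eps"] = np.where(accept[:, None], prop, cur)
            if adapt:
                ls_eps += step * (accept.astype(float) - 0.3)

            # --- block effects: conditionally independent given the rest
            Z_inv = np.linalg.inv(Z)
            eta_base = _panel_eta(state, variant, design) - state["delta"][design.l]
            cur = state["delta"]
            prop = cur + np.exp(ls_delta)[:, None] * rng.standard_normal((L, d))
            ll_cur = _panel_loglik(counts, eta_base + cur[design.l], basis)
            ll_prop = _panel_loglik(counts, eta_base + prop[design.l], basis)
            dll = np.bincount(design.l, weights=ll_prop - ll_cur, minlength=L)
            pr = (-0.5 * np.einsum("ld,de,le->l", prop, Z_inv, prop)
                  + 0.5 * np.einsum("ld,de,le->l", cur, Z_inv, cur))
            accept = np.log(rng.uniform(size=L)) < (dll + pr)
            state["delta"] = np.where(accept[:, None], prop, cur)
            if adapt:
                ls_delta += step * (accept.astype(float) - 0.3)

            # --- interweaving moves for the fixed/latent trade-off
            _interweave(state, variant, design, Z_inv, Sig_inv, rng)

            # --- covariance Gibbs draws (conjugate inverse-Wishart)
            Z = stats.invwishart.rvs(df=nu0 + L, scale=S0 + state["delta"].T @ state["delta"],
                                     random_state=rng)
            Sigma = stats.invwishart.rvs(df=nu0 + N, scale=S0 + state["eps"].T @ state["eps"],
                                         random_state=rng)

            if it >= n_warmup and (it - n_warmup) % thin == 0:
                for name, _ in blocks:
                    chain_keep[name].append(state[name].copy())
                chain_keep["delta"].append(state["delta"].copy())
                chain_keep["eps"].append(state["eps"].copy())
                chain_keep["Z"].append(Z.copy())
                chain_keep["Sigma"].append(Sigma.copy())

        for name in keep:
            keep[name].append(np.array(chain_keep[name]))

    draws = {name: np.array(v) for name, v in keep.items()}
    post = PosteriorDraws(variant=variant, basis=basis, design=design, draws=draws)
    post.diagnostics = _diagnostics(post)
    if check_diagnostics:
        bad = post.diagnostics[post.diagnostics["rhat"] > 1.01]
        if len(bad) and n_chains > 1:
            _warnings.warn(f"{len(bad)} scalar summaries have R-hat > 1.01; "
                           "increase warmup/draws", RuntimeWarning)
    return post


def _diagnostics(post: PosteriorDraws) -> pd.DataFrame:
    import arviz as az

    rows = []
    for name in [n for n, _ in _free_blocks(post.variant, post.basis.D - 1)] + ["Z", "Sigma"]:
        a = post.draws[name]
        flat = a.reshape(a.shape[0], a.shape[1], -1)
        for i in range(flat.shape[2]):
            x = flat[:, :, i]
            rows.append({
                "param": f"{name}[{i}]",
                "rhat": float(np.asarray(az.rhat(az.convert_to_dataset(x[..., None]))["x"]).ravel()[0]),
                "ess_bulk": float(np.asarray(az.ess(az.convert_to_dataset(x[..., None]))["x"]).ravel()[0]),
                "mean": float(x.mean()),
                "sd": float(x.std()),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior summaries


def treatment_composition(post: PosteriorDraws, depth: float,
                          treatment: str) -> np.ndarray:
    """Per-draw expected composition for a depth x treatment cell.

    Block and panel effects are set to zero: these are the 'large circle'
    compositions of the ternary displays.
    """
    jv = np.where(np.isclose(post.design.depth_values, depth))[0]
    if jv.size == 0:
        raise ManovaError(f"unknown depth {depth}")
    if treatment not in post.design.treatments:
        raise ManovaError(f"unknown treatment {treatment}")
    j = int(jv[0])
    k = post.design.treatments.index(treatment)
    fx = post.expand_fixed()
    eta = fx["mu"] + fx["alpha"][:, j] + fx["beta"][:, k] + fx["gamma"][:, j, k]
    return np.exp(_log_rho(eta, post.basis))


def logit_contrast(post: PosteriorDraws, part: str,
                   treatment_pair: tuple[str, str], depth: float) -> np.ndarray:
    """Posterior draws of logit(part share | k1) - logit(part share | k2).

    ``part`` is 'aurita' (first part) or 'competitors' (sum of the three
    competitor parts).  Random effects are set to zero.
    """
    if part not in ("aurita", "competitors"):
        raise ManovaError("part must be 'aurita' or 'competitors'")
    k1, k2 = treatment_pair
    out = []
    for k in (k1, k2):
        rho = treatment_composition(post, depth, k)
        share = rho[:, 0] if part == "aurita" else rho[:, 2:].sum(axis=1)
        out.append(np.log(share) - np.log1p(-share))
    return out[0] - out[1]


def effect_ternaries(post: PosteriorDraws, depth: float,
                     treatment: str) -> tuple[np.ndarray, np.ndarray]:
    """The two orthogonal 3-part projections of the cell composition.

    Returns (amalgamated, competitor-subcomposition) sample arrays, each
    (S, 3): parts (A. aurita, bare, gm(competitors)) and (Botrylloides,
    Bugula, Molgula).
    """
    rho = treatment_composition(post, depth, treatment)
    gm = np.exp(np.log(rho[:, 2:]).mean(axis=1))
    amal = np.column_stack([rho[:, 0], rho[:, 1], gm])
    amal /= amal.sum(axis=1, keepdims=True)
    sub = rho[:, 2:] / rho[:, 2:].sum(axis=1, keepdims=True)
    return amal, sub


@dataclass
class HpdRegion:
    """Boundary of a 2-D HPD region for 3-part composition samples."""

    level: float
    ilr_boundary: list[np.ndarray]      # one (m, 2) array per closed contour
    ternary_boundary: list[np.ndarray]  # matching (m, 3) compositions
    contained_fraction: float
    degenerate: bool = False


def hpd_region_2d(samples: np.ndarray, level: float = 0.95,
                  grid_size: int = 200) -> HpdRegion:
    """Smallest region holding ``level`` posterior mass, via Gaussian KDE in
    the 2-D ilr coordinates of the 3-part samples, mapped back to ternary
    coordinates with skimage contour extraction."""
    from skimage import measure

    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ManovaError("need (S, 3) composition samples")
    tb = ternary_basis()
    z = ilr(samples / samples.sum(axis=1, keepdims=True), tb)
    if np.allclose(z.std(axis=0), 0, atol=1e-12):
        return HpdRegion(level, [], [], 1.0, degenerate=True)
    kde = stats.gaussian_kde(z.T)
    dens = kde(z.T)
    thresh = np.quantile(dens, 1 - level)

    pad = 0.5 + 2 * z.std(axis=0)
    lo = z.min(axis=0) - pad
    hi = z.max(axis=0) + pad
    xs = np.linspace(lo[0], hi[0], grid_size)
    ys = np.linspace(lo[1], hi[1], grid_size)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    D = kde(np.vstack([X.ravel(), Y.ravel()])).reshape(grid_size, grid_size)

    contours = measure.find_contours(D, thresh)
    ilr_b, tern_b = [], []
    V = tb.matrix
    for c in contours:
        zx = lo[0] + c[:, 0] * (hi[0] - lo[0]) / (grid_size - 1)
        zy = lo[1] + c[:, 1] * (hi[1] - lo[1]) / (grid_size - 1)
        zz = np.column_stack([zx, zy])
        ilr_b.append(zz)
        e = np.exp(zz @ V)
        tern_b.append(e / e.sum(axis=1, keepdims=True))
    contained = float(np.mean(dens >= thresh))
    return HpdRegion(level, ilr_b, tern_b, contained)


# ---------------------------------------------------------------------------
# leave-one-cluster-out cross-validation


def _subset_dataset(data: ManovaDataset, mask: np.ndarray) -> ManovaDataset:
    return ManovaDataset(
        counts=data.counts[mask], totals=data.totals[mask],
        part_names=data.part_names, panel=data.panel[mask],
        depth=data.depth[mask], treatment=data.treatment[mask],
        block=data.block[mask])


def _block_log_predictive(post: PosteriorDraws, held: ManovaDataset,
                          n_re: int, rng: np.random.Generator,
                          max_draws: int = 400) -> tuple[float, float]:
    """log E[p(held-out block)] by Monte Carlo over draws and random effects.

    Returns (lpd, weight_ess).  One block-effect replicate is shared by all
    panels of the block within each random-effect draw.
    """
    design = Design.from_dataset(held)
    fx = post.expand_fixed()
    S = fx["mu"].shape[0]
    take = np.linspace(0, S - 1, min(max_draws, S)).astype(int)
    Z = post.stacked("Z")[take]
    Sig = post.stacked("Sigma")[take]
    eta_fixed = (fx["mu"][take][:, None, :]
                 + fx["alpha"][take][:, design.j]
                 + fx["beta"][take][:, design.k]
                 + fx["gamma"][take][:, design.j, design.k])
    P = held.n_panels
    lls = np.empty((take.size, n_re))
    counts = held.counts.astype(float)
    for s in range(take.size):
        Lz = np.linalg.cholesky(Z[s])
        Ls = np.linalg.cholesky(Sig[s])
        d = Z.shape[-1]
        deltas = rng.standard_normal((n_re, d)) @ Lz.T           # shared per block
        epss = rng.standard_normal((n_re, P, d)) @ Ls.T
        eta = eta_fixed[s][None, :, :] + deltas[:, None, :] + epss
        lls[s] = _multinomial_logpmf(counts, _log_rho(eta, post.basis)).sum(axis=1)
    flat = lls.ravel()
    lpd = float(logsumexp(flat) - np.log(flat.size))
    w = np.exp(flat - flat.max())
    ess = float(w.sum() ** 2 / (w ** 2).sum())
    return lpd, ess


def loco_cv(data: ManovaDataset, variants=("no_interaction", "full"),
            seed: int = 0, n_re: int = 100, fit_kwargs: dict | None = None,
            ess_threshold: float = 50.0) -> pd.DataFrame:
    """Leave-one-cluster-out CV: refit each variant without each block and
    score the held-out block's panels with the marginal (random effects
    integrated out by Monte Carlo) likelihood.

    Returns a table with one row per variant: elpd, delta elpd from the
    best, and SE of the difference (sqrt(B) * sd of per-block differences).
    """
    fit_kwargs = dict(fit_kwargs or {})
    fit_kwargs.setdefault("n_chains", 2)
    fit_kwargs.setdefault("n_warmup", 800)
    fit_kwargs.setdefault("n_draws", 400)
    fit_kwargs.setdefault("check_diagnostics", False)
    blocks = np.unique(data.block)
    if blocks.size < 3:
        raise ManovaError("leave-one-cluster-out CV needs >= 3 blocks")
    warnings: list[str] = []

    import zlib

    per_block = {str(v): np.empty(blocks.size) for v in variants}
    for vi, variant in enumerate(variants):
        vh = zlib.crc32(str(variant).encode())   # identical variants tie exactly
        for bi, b in enumerate(blocks):
            train = _subset_dataset(data, data.block != b)
            held = _subset_dataset(data, data.block == b)
            post = fit(train, variant=variant,
                       seed=int(np.random.SeedSequence([seed, vh, bi]).generate_state(1)[0] % (2**31)),
                       **fit_kwargs)
            rng = np.random.default_rng(np.random.SeedSequence([seed, 7, vh, bi]))
            lpd, ess = _block_log_predictive(post, held, n_re, rng)
            per_block[str(variant)][bi] = lpd
            if ess < ess_threshold:
                warnings.append(f"variant={variant} block={b}: MC weight ESS {ess:.1f}")

    elpd = {v: float(x.sum()) for v, x in per_block.items()}
    best = max(elpd, key=elpd.get)
    rows = []
    for v, x in per_block.items():
        diffs = x - per_block[best]
        se = 0.0 if v == best else float(np.sqrt(blocks.size) * diffs.std(ddof=1))
        rows.append({"model": v, "elpd_loco": elpd[v],
                     "delta_elpd": elpd[v] - elpd[best], "se_diff": se})
    out = pd.DataFrame(rows).sort_values("delta_elpd", ascending=False,
                                         ignore_index=True)
    out.attrs["warnings"] = warnings
    return out
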