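"""Sampler-correctness validation by joint-distribution (Geweke) testing.

Two simulators target the same joint distribution P(θ, Y):

* marginal-conditional — draw θ from the prior, then Y | θ from the model
  (independent exact draws);
* successive-conditional — alternate one full Gibbs scan of θ | Y with a
  redraw of Y | θ (a Markov chain whose stationary law is the same joint).

If every full conditional is correct, moments of any function g(θ) agree
between the two.  Because the Half-t/IW priors at shape 2 have no finite
variance (a deliberate weak-informativity feature), the comparison uses
bounded test functions — correlations, v/(1+v) of variances, tanh of fixed
effects — whose moments always exist.  Successive-conditional standard errors
are batch-means estimates to account for autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import Dimensions
from .distributions import HyperParams, sample_inverse_gamma, sample_inverse_wishart
from .sampler import ChainState, ModelData, StructureKind, gibbs_sweep

__all__ = ["GewekeConfig", "prior_draw", "draw_data", "geweke_compare"]


@dataclass
class GewekeConfig:
    """Small testing configuration: moderate scale hypers keep the bounded
    statistics well spread without affecting validity."""

    dims: Dimensions = Dimensions(2, 4, 1, 2)
    kind: StructureKind = StructureKind.UNSTRUCTURED
    A: float = 1.0
    sigma0_scale: float = 1.0
    n_draws: int = 20_000
    seed: int = 0

    def hyper(self) -> HyperParams:
        d = self.dims
        return HyperParams(
            A_beta=self.A,
            A_traits=np.full(d.L, self.A),
            A_E=np.full(d.I, self.A),
            A_e=np.full(d.L, self.A),
            sigma0_scale=self.sigma0_scale,
        ).resolved(d.I, d.L)

    def grm(self) -> np.ndarray:
        return 0.7 * np.eye(self.dims.J) + 0.3 * np.ones((self.dims.J, self.dims.J))


def prior_draw(cfg: GewekeConfig, rng: np.random.Generator) -> ChainState:
    """One exact draw of all parameters from the prior hierarchy."""
    d = cfg.dims
    h = cfg.hyper()
    Gg = cfg.grm()
    Lg = np.linalg.cholesky(Gg)

    a_beta = sample_inverse_gamma(0.5, 1.0 / h.A_beta**2, rng)
    sigma_beta2 = sample_inverse_gamma(h.nu_beta / 2.0, h.nu_beta / a_beta, rng)
    L0 = np.linalg.cholesky(h.Sigma0 * sigma_beta2)
    beta_flat = h.beta0 + L0 @ rng.standard_normal(d.I * d.L)
    beta = beta_flat.reshape(d.L, d.I).T

    a = np.array([sample_inverse_gamma(0.5, 1.0 / h.A_traits[l] ** 2, rng) for l in range(d.L)])
    if cfg.kind is StructureKind.UNSTRUCTURED:
        Sigma_t = sample_inverse_wishart(h.nu_t + d.L - 1, 2.0 * h.nu_t * np.diag(1.0 / a), rng)
    elif cfg.kind is StructureKind.DIAGONAL:
        Sigma_t = np.diag([sample_inverse_gamma(h.nu_t / 2.0, h.nu_t / a[l], rng) for l in range(d.L)])
    else:
        a[:] = a[0]
        Sigma_t = sample_inverse_gamma(h.nu_t / 2.0, h.nu_t / a[0], rng) * np.eye(d.L)
    Lt = np.linalg.cholesky(Sigma_t)
    b1 = Lg @ rng.standard_normal((d.J, d.L)) @ Lt.T

    a_E = np.array([sample_inverse_gamma(0.5, 1.0 / h.A_E[i] ** 2, rng) for i in range(d.I)])
    sigma_E = np.array(
        [sample_inverse_gamma(h.nu_E[i] / 2.0, h.nu_E[i] / a_E[i], rng) for i in range(d.I)]
    )
    b2 = np.empty((d.I, d.J, d.L))
    for i in range(d.I):
        b2[i] = np.sqrt(sigma_E[i]) * (Lg @ rng.standard_normal((d.J, d.L)) @ Lt.T)

    a_e = np.array([sample_inverse_gamma(0.5, 1.0 / h.A_e[l] ** 2, rng) for l in range(d.L)])
    if cfg.kind is StructureKind.UNSTRUCTURED:
        Re = sample_inverse_wishart(h.nu_e + d.L - 1, 2.0 * h.nu_e * np.diag(1.0 / a_e), rng)
    elif cfg.kind is StructureKind.DIAGONAL:
        Re = np.diag([sample_inverse_gamma(h.nu_e / 2.0, h.nu_e / a_e[l], rng) for l in range(d.L)])
    else:
        a_e[:] = a_e[0]
        Re = sample_inverse_gamma(h.nu_e / 2.0, h.nu_e / a_e[0], rng) * np.eye(d.L)

    return ChainState(beta, sigma_beta2, a_beta, b1, b2, Sigma_t, a, sigma_E, a_E, Re, a_e)


def draw_data(state: ChainState, dims: Dimensions, rng: np.random.Generator) -> np.ndarray:
    """Draw a complete response array Y | θ from the observation model."""
    Le = np.linalg.cholesky(state.Re)
    mu = state.beta[:, None, None, :] + state.b1[None, :, None, :] + state.b2[:, :, None, :]
    return mu + rng.standard_normal((dims.I, dims.J, dims.K, dims.L)) @ Le.T


def _test_functions(state: ChainState, dims: Dimensions) -> np.ndarray:
    """Bounded functionals of the parameters (finite moments under the prior)."""
    out = [np.tanh(state.beta).ravel()]
    for M in (state.Sigma_t, state.Re):
        v = np.diag(M)
        out.append(v / (1.0 + v))
        sd = np.sqrt(v)
        corr = M / np.outer(sd, sd)
        iu = np.triu_indices(dims.L, k=1)
        out.append(corr[iu])
    out.append(state.sigma_E / (1.0 + state.sigma_E))
    return np.concatenate(out)


def _test_function_names(dims: Dimensions) -> list[str]:
    names = [f"tanh_beta[{i},{l}]" for i in range(dims.I) for l in range(dims.L)]
    for blk in ("Sigma_t", "Re"):
        names += [f"{blk}_var_ratio[{l}]" for l in range(dims.L)]
        iu = np.triu_indices(dims.L, k=1)
        names += [f"{blk}_corr[{r},{c}]" for r, c in zip(*iu)]
    names += [f"sigma_E_ratio[{i}]" for i in range(dims.I)]
    return names


def _batch_se(x: np.ndarray, n_batches: int = 50) -> np.ndarray:
    n = (x.shape[0] // n_batches) * n_batches
    b = x[:n].reshape(n_batches, -1, x.shape[1]).mean(axis=1)
    return b.std(axis=0, ddof=1) / np.sqrt(n_batches)


def geweke_compare(cfg: GewekeConfig | None = None) -> pd.DataFrame:
    """Run both simulators and compare test-function means.

    Returns one row per statistic with columns ``mean_mc, se_mc, mean_sc,
    se_sc, z`` where z is the standardized discrepancy; |z| beyond ~4 for any
    statistic indicates an incorrect full conditional.
    """
    cfg = cfg or GewekeConfig()
    d = cfg.dims
    rng_mc = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    rng_sc = np.random.default_rng(np.random.SeedSequence((cfg.seed, 2)))

    mc = np.empty((cfg.n_draws, len(_test_function_names(d))))
    for s in range(cfg.n_draws):
        mc[s] = _test_functions(prior_draw(cfg, rng_mc), d)

    state = prior_draw(cfg, rng_sc)
    y0 = draw_data(state, d, rng_sc)
    model = ModelData(d, y0, cfg.grm(), cfg.hyper(), [], [], [])
    sc = np.empty_like(mc)
    for s in range(cfg.n_draws):
        model.set_response(draw_data(state, d, rng_sc))
        gibbs_sweep(state, model, cfg.kind, rng_sc)
        sc[s] = _test_functions(state, d)

    mean_mc, mean_sc = mc.mean(axis=0), sc.mean(axis=0)
    se_mc = mc.std(axis=0, ddof=1) / np.sqrt(cfg.n_draws)
    se_sc = _batch_se(sc)
    z = (mean_mc - mean_sc) / np.sqrt(se_mc**2 + se_sc**2)
    return pd.DataFrame(
        {
            "statistic": _test_function_names(d),
            "mean_mc": mean_mc,
            "se_mc": se_mc,
            "mean_sc": mean_sc,
            "se_sc": se_sc,
            "z": z,
        }
    )
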