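"""Exact Gibbs sampler for the Bayesian multi-trait multi-environment model.

The model for the stacked response (traits innermost) is

    Y = Xβ + Z1 b1 + Z2 b2 + e,
    b1 ~ N(0, Gg ⊗ Σt),   b2 ~ N(0, ΣE ⊗ Gg ⊗ Σt),   e ~ N(0, In ⊗ Re),

with β | σβ² ~ N(β0, σβ² Σ0) and Huang–Wand Half-t hierarchies on σβ², Σt,
ΣE = diag(σE1²,…,σEI²) and Re.  All full conditionals are conjugate (normal,
inverse-Wishart or inverse-gamma), so the sampler below is an exact Gibbs scan:

    1. β        — normal
    2–3. σβ², aβ — scalar IW (= IG) and IG
    4. b1, b2   — normal; the b2 conditional factorizes over environments
                  because ΣE is diagonal and Z2 is environment-partitioned
    5–6. Σt, a  — IW (df gains J from b1 and I·J from b2) and IG
    7–8. σEi², aEi — scalar IW and IG, per environment
    9–10. Re, ae — IW (df gains the observation count) and IG
    11. repeat.

Three covariance structures are supported for (Σt, Re): ``unstructured`` (full
SPD matrices), ``diagonal`` (independent per-trait variances, each with its own
Half-t), and ``standard`` (σ²·I with a single Half-t scale).  Observation
vectors with every trait missing are dropped from the likelihood; vectors with
only some traits missing keep their rows and the missing traits are redrawn
each sweep from their conditional normal, which keeps every conditional exact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .data import Dimensions, Grm, PhenotypeTable
from .distributions import (
    HyperParams,
    sample_inverse_gamma,
    sample_inverse_wishart,
    sample_mvn_from_precision,
)

__all__ = [
    "StructureKind",
    "McmcSettings",
    "ChainState",
    "ModelData",
    "PosteriorSamples",
    "init_state",
    "run_chain",
    "fit",
    "posterior_summary",
]

logger = logging.getLogger("bmtme")


class StructureKind(str, Enum):
    UNSTRUCTURED = "unstructured"
    DIAGONAL = "diagonal"
    STANDARD = "standard"


@dataclass(frozen=True)
class McmcSettings:
    """Chain length configuration.  Defaults follow the reference protocol:
    60,000 iterations with the first 30,000 discarded and no thinning."""

    iterations: int = 60_000
    burn_in: int = 30_000
    thinning: int = 1
    seed: int = 0
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thinning != 1:
            raise ValueError("thinning is fixed to 1 (posterior means do not benefit from subsampling)")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")


@dataclass
class ChainState:
    """One Gibbs state.  β is stored as (I, L); b1 as (J, L); b2 as (I, J, L)."""

    beta: np.ndarray
    sigma_beta2: float
    a_beta: float
    b1: np.ndarray
    b2: np.ndarray
    Sigma_t: np.ndarray
    a: np.ndarray
    sigma_E: np.ndarray
    a_E: np.ndarray
    Re: np.ndarray
    a_e: np.ndarray


class ModelData:
    """Validated, array-form inputs shared by all full-conditional updates."""

    def __init__(
        self,
        dims: Dimensions,
        y: np.ndarray,
        Gg: np.ndarray,
        hyper: HyperParams,
        env_order: list[str],
        line_order: list[str],
        trait_names: list[str],
    ) -> None:
        self.dims = dims
        self.y = y  # (I,J,K,L), NaN = missing
        self.obs = np.isfinite(y)
        self.incl = self.obs.any(axis=3)  # observation vectors entering the likelihood
        self.w = self.incl.astype(float)
        self.n_incl = int(self.incl.sum())
        if self.n_incl == 0:
            raise ValueError("no observation vector has any observed trait")
        self.n_env = self.incl.sum(axis=(1, 2)).astype(float)  # per environment
        self.c_line = self.incl.sum(axis=(0, 2)).astype(float)  # per line
        self.c_envline = self.incl.sum(axis=2).astype(float)  # (I,J)
        self.Gg = Gg
        c, low = cho_factor(Gg, lower=True)
        self.Gg_inv = cho_solve((c, low), np.eye(dims.J))
        self.hyper = hyper.resolved(dims.I, dims.L)
        self.Sigma0_inv = np.linalg.inv(self.hyper.Sigma0)
        self.Sigma0_inv_beta0 = self.Sigma0_inv @ self.hyper.beta0
        self.env_order = env_order
        self.line_order = line_order
        self.trait_names = trait_names

        # complete response: excluded vectors are 0 (and weighted out);
        # missing traits inside included vectors start at the environment-trait mean
        self.y_aug = np.where(self.obs, y, 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing slices are fine
            cell_mean = np.nanmean(np.where(self.obs, y, np.nan), axis=(1, 2))  # (I,L)
        cell_mean = np.nan_to_num(cell_mean)
        fill = self.incl[:, :, :, None] & ~self.obs
        self.y_aug[fill] = np.broadcast_to(cell_mean[:, None, None, :], y.shape)[fill]

        # group partially observed vectors by their missingness pattern
        self.partial_groups: list[tuple[np.ndarray, np.ndarray, tuple]] = []
        partial = self.incl & ~self.obs.all(axis=3)
        if partial.any():
            idx = np.argwhere(partial)
            patterns = self.obs[partial]
            uniq, inverse = np.unique(patterns, axis=0, return_inverse=True)
            for g, pat in enumerate(uniq):
                sel = idx[inverse == g]
                o = np.flatnonzero(pat)
                m = np.flatnonzero(~pat)
                self.partial_groups.append((o, m, (sel[:, 0], sel[:, 1], sel[:, 2])))

    @classmethod
    def prepare(
        cls,
        pheno: PhenotypeTable,
        grm: Grm,
        hyper: HyperParams | None = None,
        dims: Dimensions | None = None,
        train_mask: np.ndarray | None = None,
    ) -> "ModelData":
        """Arrange a phenotype table and GRM for sampling.

        ``train_mask`` (boolean (I,J,K,L), True = usable) further masks
        observed cells, as in cross-validation.
        """
        dims = dims or pheno.dims
        if set(grm.line_labels) != set(pheno.line_order):
            raise ValueError("GRM line labels do not match the phenotype table")
        order = [grm.line_labels.index(g) for g in pheno.line_order]
        Gg = grm.matrix[np.ix_(order, order)]
        y = pheno.to_arrays(dims)
        if train_mask is not None:
            if train_mask.shape != y.shape:
                raise ValueError("train_mask shape does not match (I,J,K,L)")
            y = np.where(train_mask, y, np.nan)
        Gg = Grm(Gg, list(pheno.line_order)).invertible_matrix()
        return cls(dims, y, Gg, hyper or HyperParams(), pheno.env_order, pheno.line_order, pheno.trait_names)

    def set_response(self, y: np.ndarray) -> None:
        """Replace the (fully observed) response in place — used by the
        joint-distribution validator, which redraws data each sweep."""
        if self.partial_groups or not self.obs.all():
            raise ValueError("set_response requires a fully observed layout")
        self.y = y
        self.y_aug = y.copy()


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws of every model parameter."""

    beta: np.ndarray  # (S,I,L)
    sigma_beta2: np.ndarray  # (S,)
    a_beta: np.ndarray  # (S,)
    b1: np.ndarray  # (S,J,L)
    b2: np.ndarray  # (S,I,J,L)
    Sigma_t: np.ndarray  # (S,L,L)
    a: np.ndarray  # (S,L)
    sigma_E: np.ndarray  # (S,I)
    a_E: np.ndarray  # (S,I)
    Re: np.ndarray  # (S,L,L)
    a_e: np.ndarray  # (S,L)
    settings: McmcSettings
    kind: StructureKind
    dims: Dimensions
    env_order: list[str] = field(default_factory=list)
    line_order: list[str] = field(default_factory=list)
    trait_names: list[str] = field(default_factory=list)

    @property
    def n_retained(self) -> int:
        return self.beta.shape[0]

    def predictor_mean(self) -> np.ndarray:
        """Posterior mean of the linear predictor Xβ + Z1 b1 + Z2 b2, per
        (environment, line, trait) cell (replicates share the same value)."""
        beta = self.beta.mean(axis=0)
        b1 = self.b1.mean(axis=0)
        b2 = self.b2.mean(axis=0)
        return beta[:, None, :] + b1[None, :, :] + b2

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("beta", "sigma_beta2", "a_beta", "b1", "b2", "Sigma_t", "a", "sigma_E", "a_E", "Re", "a_e"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["kind"] = self.kind.value
            f.attrs["iterations"] = self.settings.iterations
            f.attrs["burn_in"] = self.settings.burn_in
            f.attrs["seed"] = self.settings.seed
            f.attrs["dims"] = [self.dims.I, self.dims.J, self.dims.K, self.dims.L]
            f.attrs["env_order"] = self.env_order
            f.attrs["line_order"] = self.line_order
            f.attrs["trait_names"] = self.trait_names


# ---------------------------------------------------------------------------
# full-conditional updates


def init_state(model: ModelData, kind: StructureKind = StructureKind.UNSTRUCTURED) -> ChainState:
    """Deterministic starting point: β at environment-trait means of the data,
    random effects at zero, all (co)variances at identity/one."""
    d = model.dims
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing slices are fine
        beta = np.nanmean(np.where(model.obs, model.y, np.nan), axis=(1, 2))
    beta = np.nan_to_num(beta)
    return ChainState(
        beta=beta,
        sigma_beta2=1.0,
        a_beta=1.0,
        b1=np.zeros((d.J, d.L)),
        b2=np.zeros((d.I, d.J, d.L)),
        Sigma_t=np.eye(d.L),
        a=np.ones(d.L),
        sigma_E=np.ones(d.I),
        a_E=np.ones(d.I),
        Re=np.eye(d.L),
        a_e=np.ones(d.L),
    )


def augment_missing(state: ChainState, model: ModelData, rng: np.random.Generator) -> None:
    """Redraw missing traits of partially observed vectors from their
    conditional normal given the observed traits and the current parameters."""
    if not model.partial_groups:
        return
    mu_cell = state.beta[:, None, :] + state.b1[None, :, :] + state.b2  # (I,J,L)
    for o, m, (ii, jj, kk) in model.partial_groups:
        mu = mu_cell[ii, jj, :]
        Roo = state.Re[np.ix_(o, o)]
        Rmo = state.Re[np.ix_(m, o)]
        Rmm = state.Re[np.ix_(m, m)]
        c, low = cho_factor(Roo, lower=True)
        gain = cho_solve((c, low), Rmo.T).T  # Rmo Roo^{-1}
        resid_o = model.y_aug[ii, jj, kk][:, o] - mu[:, o]
        cond_mean = mu[:, m] + resid_o @ gain.T
        cond_cov = Rmm - gain @ Rmo.T
        Lc = np.linalg.cholesky(cond_cov)
        z = rng.standard_normal((len(ii), len(m)))
        vals = cond_mean + z @ Lc.T
        yk = model.y_aug[ii, jj, kk]
        yk[:, m] = vals
        model.y_aug[ii, jj, kk] = yk


def sample_beta(state: ChainState, model: ModelData, rng: np.random.Generator) -> None:
    """Normal full conditional for the environment-by-trait fixed effects."""
    d = model.dims
    Re_inv = np.linalg.inv(state.Re)
    r = model.y_aug - state.b1[None, :, None, :] - state.b2[:, :, None, :]
    s = np.einsum("ijk,ijkl->il", model.w, r)  # (I,L)
    IL = d.I * d.L
    P = model.Sigma0_inv / state.sigma_beta2
    lin = model.Sigma0_inv_beta0 / state.sigma_beta2
    P = P.copy()
    lin = lin.copy()
    for i in range(d.I):
        idx = np.arange(d.L) * d.I + i  # trait-major flat layout
        P[np.ix_(idx, idx)] += model.n_env[i] * Re_inv
        lin[idx] += Re_inv @ s[i]
    draw = sample_mvn_from_precision(P, lin, rng)
    state.beta = draw.reshape(d.L, d.I).T


def sample_sigma_beta_and_abeta(state: ChainState, model: ModelData, rng: np.random.Generator) -> None:
    """Scalar-IW (=IG) conditional for σβ², then the IG conditional for aβ."""
    h = model.hyper
    d = model.dims
    beta_flat = state.beta.T.ravel()  # trait-major, matching beta0/Sigma0
    diff = beta_flat - h.beta0
    q = float(diff @ model.Sigma0_inv @ diff)
    state.sigma_beta2 = sample_inverse_gamma(
        h.nu_beta / 2.0 + d.I * d.L / 2.0, h.nu_beta / state.a_beta + q / 2.0, rng
    )
    state.a_beta = sample_inverse_gamma(
        0.5 + h.nu_beta / 2.0, 1.0 / h.A_beta**2 + h.nu_beta / state.sigma_beta2, rng
    )


def sample_random_effects(h_index: int, state: ChainState, model: ModelData, rng: np.random.Generator) -> None:
    """Normal full conditionals for b1 (h_index=1) or b2 (h_index=2).

    The b2 conditional splits into I independent (J·L)-blocks because ΣE is
    diagonal and each observation touches a single environment.
    """
    d = model.dims
    Re_inv = np.linalg.inv(state.Re)
    Sigt_inv = np.linalg.inv(state.Sigma_t)
    prior_prec = np.kron(model.Gg_inv, Sigt_inv)
    if h_index == 1:
        r = model.y_aug - state.beta[:, None, None, :] - state.b2[:, :, None, :]
        s = np.einsum("ijk,ijkl->jl", model.w, r)  # (J,L)
        P = prior_prec.copy()
        view = P.reshape(d.J, d.L, d.J, d.L)
        jj = np.arange(d.J)
        view[jj, :, jj, :] += model.c_line[:, None, None] * Re_inv
        lin = (s @ Re_inv).ravel()
        state.b1 = sample_mvn_from_precision(P, lin, rng).reshape(d.J, d.L)
    elif h_index == 2:
        r = model.y_aug - state.beta[:, None, None, :] - state.b1[None, :, None, :]
        s = np.einsum("ijk,ijkl->ijl", model.w, r)  # (I,J,L)
        jj = np.arange(d.J)
        b2 = np.empty_like(state.b2)
        for i in range(d.I):
            P = prior_prec / state.sigma_E[i]
            view = P.reshape(d.J, d.L, d.J, d.L)
            view[jj, :, jj, :] += model.c_envline[i][:, None, None] * Re_inv
            lin = (s[i] @ Re_inv).ravel()
            b2[i] = sample_mvn_from_precision(P, lin, rng).reshape(d.J, d.L)
        state.b2 = b2
    else:
        raise ValueError("h_index must be 1 or 2")


def _trait_scatter(state: ChainState, model: ModelData) -> tuple[np.ndarray, np.ndarray]:
    """S1 = B1ᵀ Gg⁻¹ B1 and S2 = Σ_i σEi⁻² B2iᵀ Gg⁻¹ B2i (both L×L)."""
    S1 = state.b1.T @ model.Gg_inv @ state.b1
    GB = np.einsum("jm,iml->ijl", model.Gg_inv, state.b2)
    S2 = np.einsum("ijl,ijm,i->lm", state.b2, GB, 1.0 / state.sigma_E)
    return S1, S2


def sample_trait_covariance(
    state: ChainState, model: ModelData, kind: StructureKind, rng: np.random.Generator
) -> None:
    """Conditional for the genetic trait covariance Σt.

    Both b1 and b2 inform Σt (it appears in Gg⊗Σt and ΣE⊗Gg⊗Σt), adding J and
    I·J to the inverse-Wishart degrees of freedom respectively.
    """
    d = model.dims
    h = model.hyper
    S1, S2 = _trait_scatter(state, model)
    count = d.J + d.I * d.J
    if kind is StructureKind.UNSTRUCTURED:
        kappa = h.nu_t + d.L - 1 + count
        B = 2.0 * h.nu_t * np.diag(1.0 / state.a) + S1 + S2
        state.Sigma_t = sample_inverse_wishart(kappa, B, rng)
    elif kind is StructureKind.DIAGONAL:
        diag = np.array(
            [
                sample_inverse_gamma(
                    h.nu_t / 2.0 + count / 2.0,
                    h.nu_t / state.a[l] + (S1[l, l] + S2[l, l]) / 2.0,
                    rng,
                )
                for l in range(d.L)
            ]
        )
        state.Sigma_t = np.diag(diag)
    else:  # STANDARD: Sigma_t = sigma_t^2 I
        sigma_t2 = sample_inverse_gamma(
            h.nu_t / 2.0 + count * d.L / 2.0,
            h.nu_t / state.a[0] + np.trace(S1 + S2) / 2.0,
            rng,
        )
        state.Sigma_t = sigma_t2 * np.eye(d.L)


def sample_trait_aux(state: ChainState, model: ModelData, kind: StructureKind, rng: np.random.Generator) -> None:
    """IG conditionals for the Half-t auxiliary scales a_l of Σt."""
    d = model.dims
    h = model.hyper
    if kind is StructureKind.UNSTRUCTURED:
        Sigt_inv = np.linalg.inv(state.Sigma_t)
        state.a = np.array(
            [
                sample_inverse_gamma(
                    0.5 + (h.nu_t + d.L - 1) / 2.0,
                    1.0 / h.A_traits[l] ** 2 + h.nu_t * Sigt_inv[l, l],
                    rng,
                )
                for l in range(d.L)
            ]
        )
    elif kind is StructureKind.DIAGONAL:
        state.a = np.array(
            [
                sample_inverse_gamma(
                    0.5 + h.nu_t / 2.0,
                    1.0 / h.A_traits[l] ** 2 + h.nu_t / state.Sigma_t[l, l],
                    rng,
                )
                for l in range(d.L)
            ]
        )
    else:
        a = sample_inverse_gamma(
            0.5 + h.nu_t / 2.0, 1.0 / h.A_traits[0] ** 2 + h.nu_t / state.Sigma_t[0, 0], rng
        )
        state.a = np.full(d.L, a)


def sample_env_variances(state: ChainState, model: ModelData, rng: np.random.Generator) -> None:
    """Scalar-IW conditionals for each σEi², then IG conditionals for aEi."""
    d = model.dims
    h = model.hyper
    Sigt_inv = np.linalg.inv(state.Sigma_t)
    for i in range(d.I):
        S2i = state.b2[i].T @ model.Gg_inv @ state.b2[i]
        q = float((S2i * Sigt_inv).sum())
        state.sigma_E[i] = sample_inverse_gamma(
            h.nu_E[i] / 2.0 + d.J * d.L / 2.0, h.nu_E[i] / state.a_E[i] + q / 2.0, rng
        )
        state.a_E[i] = sample_inverse_gamma(
            0.5 + h.nu_E[i] / 2.0, 1.0 / h.A_E[i] ** 2 + h.nu_E[i] / state.sigma_E[i], rng
        )


def sample_residual_covariance(
    state: ChainState, model: ModelData, kind: StructureKind, rng: np.random.Generator
) -> None:
    """Conditional for Re from per-observation residual outer products, then
    the IG conditionals for its Half-t auxiliaries ae_l."""
    d = model.dims
    h = model.hyper
    e = model.y_aug - state.beta[:, None, None, :] - state.b1[None, :, None, :] - state.b2[:, :, None, :]
    Se = np.einsum("ijk,ijkl,ijkm->lm", model.w, e, e)
    if kind is StructureKind.UNSTRUCTURED:
        kappa = h.nu_e + d.L - 1 + model.n_incl
        B = 2.0 * h.nu_e * np.diag(1.0 / state.a_e) + Se
        state.Re = sample_inverse_wishart(kappa, B, rng)
        Re_inv = np.linalg.inv(state.Re)
        state.a_e = np.array(
            [
                sample_inverse_gamma(
                    0.5 + (h.nu_e + d.L - 1) / 2.0,
                    1.0 / h.A_e[l] ** 2 + h.nu_e * Re_inv[l, l],
                    rng,
                )
                for l in range(d.L)
            ]
        )
    elif kind is StructureKind.DIAGONAL:
        diag = np.array(
            [
                sample_inverse_gamma(
                    h.nu_e / 2.0 + model.n_incl / 2.0,
                    h.nu_e / state.a_e[l] + Se[l, l] / 2.0,
                    rng,
                )
                for l in range(d.L)
            ]
        )
        state.Re = np.diag(diag)
        state.a_e = np.array(
            [
                sample_inverse_gamma(
                    0.5 + h.nu_e / 2.0, 1.0 / h.A_e[l] ** 2 + h.nu_e / diag[l], rng
                )
                for l in range(d.L)
            ]
        )
    else:
        sigma_e2 = sample_inverse_gamma(
            h.nu_e / 2.0 + model.n_incl * d.L / 2.0,
            h.nu_e / state.a_e[0] + np.trace(Se) / 2.0,
            rng,
        )
        state.Re = sigma_e2 * np.eye(d.L)
        ae = sample_inverse_gamma(0.5 + h.nu_e / 2.0, 1.0 / h.A_e[0] ** 2 + h.nu_e / sigma_e2, rng)
        state.a_e = np.full(d.L, ae)


def gibbs_sweep(state: ChainState, model: ModelData, kind: StructureKind, rng: np.random.Generator) -> None:
    """One full scan in the prescribed order (steps 1–10 plus augmentation)."""
    augment_missing(state, model, rng)
    sample_beta(state, model, rng)
    sample_sigma_beta_and_abeta(state, model, rng)
    sample_random_effects(1, state, model, rng)
    sample_random_effects(2, state, model, rng)
    sample_trait_covariance(state, model, kind, rng)
    sample_trait_aux(state, model, kind, rng)
    sample_env_variances(state, model, rng)
    sample_residual_covariance(state, model, kind, rng)


_STEP_FNS = (
    ("augment_missing", lambda st, m, k, r: augment_missing(st, m, r)),
    ("sample_beta", lambda st, m, k, r: sample_beta(st, m, r)),
    ("sample_sigma_beta_and_abeta", lambda st, m, k, r: sample_sigma_beta_and_abeta(st, m, r)),
    ("sample_b1", lambda st, m, k, r: sample_random_effects(1, st, m, r)),
    ("sample_b2", lambda st, m, k, r: sample_random_effects(2, st, m, r)),
    ("sample_trait_covariance", lambda st, m, k, r: sample_trait_covariance(st, m, k, r)),
    ("sample_trait_aux", lambda st, m, k, r: sample_trait_aux(st, m, k, r)),
    ("sample_env_variances", lambda st, m, k, r: sample_env_variances(st, m, r)),
    ("sample_residual_covariance", lambda st, m, k, r: sample_residual_covariance(st, m, k, r)),
)


def _check_finite(state: ChainState, step: str, iteration: int) -> None:
    for name in ("beta", "b1", "b2", "Sigma_t", "sigma_E", "Re", "a", "a_E", "a_e"):
        if not np.isfinite(getattr(state, name)).all():
            raise FloatingPointError(
                f"non-finite {name} after step {step!r} at iteration {iteration}"
            )
    if not (np.isfinite(state.sigma_beta2) and np.isfinite(state.a_beta)):
        raise FloatingPointError(f"non-finite scalar after step {step!r} at iteration {iteration}")


def run_chain(
    model: ModelData,
    kind: StructureKind = StructureKind.UNSTRUCTURED,
    settings: McmcSettings | None = None,
    log_every: int = 0,
) -> PosteriorSamples:
    """Run one Gibbs chain and retain every post-burn-in state (thinning 1)."""
    settings = settings or McmcSettings()
    d = model.dims
    rng = np.random.default_rng(np.random.SeedSequence(settings.seed))
    state = init_state(model, kind)
    S = settings.iterations - settings.burn_in
    out = PosteriorSamples(
        beta=np.empty((S, d.I, d.L)),
        sigma_beta2=np.empty(S),
        a_beta=np.empty(S),
        b1=np.empty((S, d.J, d.L)),
        b2=np.empty((S, d.I, d.J, d.L)),
        Sigma_t=np.empty((S, d.L, d.L)),
        a=np.empty((S, d.L)),
        sigma_E=np.empty((S, d.I)),
        a_E=np.empty((S, d.I)),
        Re=np.empty((S, d.L, d.L)),
        a_e=np.empty((S, d.L)),
        settings=settings,
        kind=kind,
        dims=d,
        env_order=list(model.env_order),
        line_order=list(model.line_order),
        trait_names=list(model.trait_names),
    )
    for it in range(settings.iterations):
        for step_name, step in _STEP_FNS:
            try:
                step(state, model, kind, rng)
            except Exception as exc:
                raise RuntimeError(f"Gibbs step {step_name!r} failed at iteration {it}: {exc}") from exc
        _check_finite(state, "sweep", it)
        if log_every and (it + 1) % log_every == 0:
            logger.info("iteration %d/%d", it + 1, settings.iterations)
        s = it - settings.burn_in
        if s >= 0:
            out.beta[s] = state.beta
            out.sigma_beta2[s] = state.sigma_beta2
            out.a_beta[s] = state.a_beta
            out.b1[s] = state.b1
            out.b2[s] = state.b2
            out.Sigma_t[s] = state.Sigma_t
            out.a[s] = state.a
            out.sigma_E[s] = state.sigma_E
            out.a_E[s] = state.a_E
            out.Re[s] = state.Re
            out.a_e[s] = state.a_e
    return out


def fit(
    pheno: PhenotypeTable,
    grm: Grm,
    hyper: HyperParams | None = None,
    kind: StructureKind = StructureKind.UNSTRUCTURED,
    settings: McmcSettings | None = None,
    train_mask: np.ndarray | None = None,
    log_every: int = 0,
) -> PosteriorSamples:
    """Prepare the data and run one chain (convenience wrapper)."""
    model = ModelData.prepare(pheno, grm, hyper, train_mask=train_mask)
    return run_chain(model, kind, settings, log_every=log_every)


def run_chains(
    model: ModelData,
    kind: StructureKind = StructureKind.UNSTRUCTURED,
    settings: McmcSettings | None = None,
) -> list[PosteriorSamples]:
    """Run ``settings.n_chains`` chains with independent child seed streams."""
    settings = settings or McmcSettings()
    children = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    out = []
    for ss in children:
        child_seed = int(ss.generate_state(1)[0] % 2**31)
        out.append(run_chain(model, kind, replace(settings, seed=child_seed, n_chains=1)))
    return out


# ---------------------------------------------------------------------------
# summaries


def posterior_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior means and SDs per parameter, blocked as genetic covariance
    (Sigma_t), residual covariance (Re), environment variances (Sigma_E) and
    fixed effects (beta)."""
    if samples.n_retained < 2:
        raise ValueError("need at least two retained draws to summarize")
    traits = samples.trait_names or [f"T{l + 1}" for l in range(samples.dims.L)]
    envs = samples.env_order or [f"E{i + 1}" for i in range(samples.dims.I)]
    rows = []
    for name, arr, rl, cl in (
        ("Sigma_t", samples.Sigma_t, traits, traits),
        ("Re", samples.Re, traits, traits),
    ):
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
        for r, rn in enumerate(rl):
            for c, cn in enumerate(cl):
                if c < r:
                    continue  # upper triangle, Table-style
                rows.append((name, rn, cn, mean[r, c], sd[r, c]))
    mean = samples.sigma_E.mean(axis=0)
    sd = samples.sigma_E.std(axis=0, ddof=1)
    for i, en in enumerate(envs):
        rows.append(("Sigma_E", en, en, mean[i], sd[i]))
    mean = samples.beta.mean(axis=0)
    sd = samples.beta.std(axis=0, ddof=1)
    for i, en in enumerate(envs):
        for l, tn in enumerate(traits):
            rows.append(("beta", en, tn, mean[i, l], sd[i, l]))
    return pd.DataFrame(rows, columns=["block", "row", "col", "mean", "sd"])


def split_rhat_ess(x: np.ndarray) -> tuple[float, float]:
    """Split-chain R-hat and a crude effective sample size for a 1-D chain.

    Reported on request as a convergence diagnostic; the sampler itself runs
    for a fixed number of iterations.
    """
    x = np.asarray(x, float)
    n = x.size // 2
    halves = np.stack([x[:n], x[n : 2 * n]])
    m = halves.mean(axis=1)
    W = halves.var(axis=1, ddof=1).mean()
    B = n * np.var(m, ddof=1)
    var_plus = (n - 1) / n * W + B / n
    rhat = float(np.sqrt(var_plus / W)) if W > 0 else 1.0
    # initial-positive-sequence autocorrelation sum on the pooled chain
    xc = x - x.mean()
    acov = np.correlate(xc, xc, mode="full")[x.size - 1 :] / x.size
    rho = acov / acov[0] if acov[0] > 0 else np.zeros_like(acov)
    s = 1.0
    for t in range(1, min(1000, x.size - 1)):
        if rho[t] + (rho[t + 1] if t + 1 < rho.size else 0.0) < 0:
            break
        s += 2.0 * rho[t]
    ess = float(x.size / max(s, 1.0))
    return rhat, ess
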