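"""Random-variate kernels and prior conventions.

The inverse-Wishart convention throughout the package is the density

    P(Ω) ∝ |B|^{κ/2} |Ω|^{-(κ+p+1)/2} exp(-tr(B Ω⁻¹) / 2),

i.e. shape κ and scale matrix B, with mean B/(κ−p−1) for κ > p+1.  For p = 1
this reduces to an inverse-gamma IG(κ/2, B/2).  Covariance matrices receive the
Huang–Wand scale-mixture prior: Σ | a ~ IW(ν+p−1, 2ν·diag(1/a)) with
independent a_l ~ IG(1/2, 1/A_l²), which makes each prior standard deviation
√Σ_ll a Half-t(ν, A_l) and — at ν = 2 — each prior correlation uniform on
(−1, 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.linalg import cho_factor, cho_solve, solve_triangular

__all__ = [
    "HyperParams",
    "sample_inverse_wishart",
    "sample_inverse_gamma",
    "sample_mvn_from_precision",
    "half_t_cdf",
    "half_t_ppf",
]


@dataclass
class HyperParams:
    """Hyper-parameters of the hierarchical Half-t priors.

    Defaults are the weakly informative settings used throughout: all shape
    parameters ν = 2, all scale hypers A = 100,000, β0 = 0 and Σ0 = 10,000·I.
    ``beta0``/``Sigma0`` are laid out trait-major to match the fixed-effect
    vector β = [β(1)ᵀ, …, β(L)ᵀ]ᵀ.
    """

    nu_beta: float = 2.0
    A_beta: float = 1e5
    nu_t: float = 2.0
    A_traits: np.ndarray | None = None  # length L
    nu_E: np.ndarray | None = None  # length I
    A_E: np.ndarray | None = None  # length I
    nu_e: float = 2.0
    A_e: np.ndarray | None = None  # length L
    beta0: np.ndarray | None = None  # length I*L, trait-major
    Sigma0: np.ndarray | None = None  # (I*L, I*L)
    sigma0_scale: float = 1e4  # used for the default Sigma0 = sigma0_scale * I

    def resolved(self, I: int, L: int) -> "HyperParams":
        """Fill per-dimension defaults for a model with I environments, L traits."""
        h = HyperParams(
            nu_beta=float(self.nu_beta),
            A_beta=float(self.A_beta),
            nu_t=float(self.nu_t),
            A_traits=np.full(L, 1e5) if self.A_traits is None else np.asarray(self.A_traits, float),
            nu_E=np.full(I, 2.0) if self.nu_E is None else np.asarray(self.nu_E, float),
            A_E=np.full(I, 1e5) if self.A_E is None else np.asarray(self.A_E, float),
            nu_e=float(self.nu_e),
            A_e=np.full(L, 1e5) if self.A_e is None else np.asarray(self.A_e, float),
            beta0=np.zeros(I * L) if self.beta0 is None else np.asarray(self.beta0, float),
            Sigma0=(
                float(self.sigma0_scale) * np.eye(I * L)
                if self.Sigma0 is None
                else np.asarray(self.Sigma0, float)
            ),
            sigma0_scale=float(self.sigma0_scale),
        )
        if h.A_traits.shape != (L,) or h.A_e.shape != (L,):
            raise ValueError("A_traits and A_e must have one entry per trait")
        if h.nu_E.shape != (I,) or h.A_E.shape != (I,):
            raise ValueError("nu_E and A_E must have one entry per environment")
        if h.beta0.shape != (I * L,) or h.Sigma0.shape != (I * L, I * L):
            raise ValueError("beta0 / Sigma0 are inconsistent with I*L")
        for name in ("nu_beta", "nu_t", "nu_e"):
            if getattr(h, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if (h.nu_E <= 0).any() or (h.A_E <= 0).any() or (h.A_traits <= 0).any() or (h.A_e <= 0).any() or h.A_beta <= 0:
            raise ValueError("all shape/scale hypers must be positive")
        return h

    @classmethod
    def from_config(cls, cfg: dict) -> "HyperParams":
        """Build from the YAML/JSON config keys (nu_beta, A_beta, nu_t, ...)."""
        kw = {}
        scalar = {"nu_beta", "A_beta", "nu_t", "nu_e"}
        arrays = {"A_traits", "nu_E", "A_E", "A_e", "beta0"}
        for key, val in cfg.items():
            if key == "seed":
                continue
            if key == "Sigma0_scale":
                kw["sigma0_scale"] = float(val)
            elif key in scalar:
                kw[key] = float(val)
            elif key in arrays:
                kw[key] = None if val is None else np.asarray(val, float)
            else:
                raise ValueError(f"unknown hyper-parameter config key {key!r}")
        return cls(**kw)


def sample_inverse_wishart(kappa: float, B: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw Ω ~ IW(κ, B) under the package's shape/scale convention.

    Requires κ > p − 1 and SPD B; the draw is symmetric positive definite.
    """
    B = np.asarray(B, dtype=float)
    p = B.shape[0]
    if kappa <= p - 1:
        raise ValueError(f"inverse-Wishart shape must exceed p-1={p - 1}, got {kappa}")
    try:
        np.linalg.cholesky(B)
    except np.linalg.LinAlgError as exc:
        raise ValueError("inverse-Wishart scale matrix is not SPD") from exc
    if p == 1:
        return np.array([[sample_inverse_gamma(kappa / 2.0, B[0, 0] / 2.0, rng)]])
    draw = stats.invwishart.rvs(df=kappa, scale=B, random_state=rng)
    return 0.5 * (draw + draw.T)


def sample_inverse_gamma(shape: float, scale: float, rng: np.random.Generator) -> float:
    """Draw x with density ∝ x^{-shape-1} exp(-scale/x); 1/x ~ Gamma(shape, rate=scale)."""
    if shape <= 0 or scale <= 0:
        raise ValueError("inverse-gamma shape and scale must be positive")
    return scale / rng.gamma(shape)


def sample_mvn_from_precision(
    precision: np.ndarray, linear: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw from N(P⁻¹ t, P⁻¹) given precision P and linear term t.

    One Cholesky factorization serves both the mean solve and the noise
    rotation; no explicit inverse is formed.
    """
    P = np.asarray(precision, dtype=float)
    try:
        c, low = cho_factor(P, lower=True)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "precision matrix is not positive definite (ill-conditioned full conditional)"
        ) from exc
    mean = cho_solve((c, low), np.asarray(linear, dtype=float))
    z = rng.standard_normal(P.shape[0])
    return mean + solve_triangular(c, z, lower=True, trans="T")


def half_t_cdf(x: np.ndarray, nu: float, A: float) -> np.ndarray:
    """CDF of the Half-t distribution with ``nu`` degrees of freedom and scale ``A``."""
    x = np.asarray(x, dtype=float)
    return np.where(x < 0, 0.0, 2.0 * stats.t.cdf(x / A, df=nu) - 1.0)


def half_t_ppf(q: np.ndarray, nu: float, A: float) -> np.ndarray:
    """Quantile function of the Half-t(nu, A) distribution."""
    return A * stats.t.ppf((np.asarray(q, float) + 1.0) / 2.0, df=nu)
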