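"""Phenotype and marker containers, genomic relationships, and model design matrices.

The three-way layout used throughout the package is environment-major, then line,
then replicate, with the L traits innermost: the observation of trait ``l`` on
replicate ``k`` of line ``j`` in environment ``i`` sits at flat position
``(((i*J + j)*K + k)*L + l)`` (0-based).  This is the unique ordering under which
the separable random-effect priors ``b1 ~ N(0, Gg ⊗ Σt)`` (lines outer, traits
inner) and ``b2 ~ N(0, ΣE ⊗ Gg ⊗ Σt)`` (environments outermost) line up with the
incidence matrices built here.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "Dimensions",
    "PhenotypeTable",
    "MarkerMatrix",
    "Grm",
    "DesignMatrices",
    "encode_markers",
    "compute_grm",
    "arrange_threeway",
    "arrange_inverse",
    "build_design",
    "flat_index",
    "read_phenotypes",
    "read_markers",
    "read_grm",
]

KEY_COLUMNS = ("env", "line", "rep")


@dataclass(frozen=True)
class Dimensions:
    """Index bounds of the three-way layout.

    I environments, J lines, K replicates per line per environment, L traits;
    n = I*J*K observations per trait.
    """

    I: int
    J: int
    K: int
    L: int

    def __post_init__(self) -> None:
        for name in ("I", "J", "K", "L"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"dimension {name} must be a positive integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.I * self.J * self.K


def flat_index(i: int, j: int, k: int, l: int, dims: Dimensions) -> int:
    """0-based position of (environment i, line j, replicate k, trait l)."""
    return ((i * dims.J + j) * dims.K + k) * dims.L + l


@dataclass
class PhenotypeTable:
    """Long-format phenotype records with declared factor orders.

    ``df`` has columns ``env, line, rep, <trait...>``; missing trait values are
    NaN.  Factor orders default to order of first appearance.
    """

    df: pd.DataFrame
    env_order: list[str]
    line_order: list[str]
    trait_names: list[str]

    def __post_init__(self) -> None:
        for c in KEY_COLUMNS:
            if c not in self.df.columns:
                raise ValueError(f"phenotype table lacks required column {c!r}")
        if not self.trait_names:
            raise ValueError("phenotype table has no trait columns")
        keys = self.df[list(KEY_COLUMNS)]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (env, line, rep) key: {dup}")
        bad_env = set(self.df["env"]) - set(self.env_order)
        if bad_env:
            raise ValueError(f"environment labels not in declared order: {sorted(bad_env)}")
        bad_line = set(self.df["line"]) - set(self.line_order)
        if bad_line:
            raise ValueError(f"line labels not in declared order: {sorted(bad_line)}")
        if not np.isfinite(self.df[self.trait_names].to_numpy(dtype=float)).any():
            raise ValueError("phenotype table contains no non-missing trait value")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        env_order: list[str] | None = None,
        line_order: list[str] | None = None,
        trait_names: list[str] | None = None,
    ) -> "PhenotypeTable":
        df = df.copy()
        df["env"] = df["env"].astype(str)
        df["line"] = df["line"].astype(str)
        df["rep"] = df["rep"].astype(int)
        if trait_names is None:
            trait_names = [c for c in df.columns if c not in KEY_COLUMNS]
        df[trait_names] = df[trait_names].apply(pd.to_numeric)
        if env_order is None:
            env_order = list(dict.fromkeys(df["env"]))
        if line_order is None:
            line_order = list(dict.fromkeys(df["line"]))
        return cls(df, list(env_order), list(line_order), list(trait_names))

    @property
    def dims(self) -> Dimensions:
        K = int(self.df.groupby(["env", "line"])["rep"].count().max())
        return Dimensions(len(self.env_order), len(self.line_order), K, len(self.trait_names))

    def to_arrays(self, dims: Dimensions | None = None) -> np.ndarray:
        """Return a (I, J, K, L) float array with NaN for missing cells.

        Replicate indices must be 1..K.
        """
        dims = dims or self.dims
        y = np.full((dims.I, dims.J, dims.K, dims.L), np.nan)
        env_ix = {e: i for i, e in enumerate(self.env_order)}
        line_ix = {g: j for j, g in enumerate(self.line_order)}
        ii = self.df["env"].map(env_ix).to_numpy()
        jj = self.df["line"].map(line_ix).to_numpy()
        kk = self.df["rep"].to_numpy() - 1
        if (kk < 0).any() or (kk >= dims.K).any():
            raise ValueError(f"replicate indices must lie in 1..{dims.K}")
        y[ii, jj, kk, :] = self.df[self.trait_names].to_numpy(dtype=float)
        return y

    @classmethod
    def from_arrays(
        cls,
        y: np.ndarray,
        env_order: list[str] | None = None,
        line_order: list[str] | None = None,
        trait_names: list[str] | None = None,
    ) -> "PhenotypeTable":
        I, J, K, L = y.shape
        env_order = env_order or [f"E{i + 1}" for i in range(I)]
        line_order = line_order or [f"L{j + 1}" for j in range(J)]
        trait_names = trait_names or [f"T{l + 1}" for l in range(L)]
        ii, jj, kk = np.meshgrid(np.arange(I), np.arange(J), np.arange(K), indexing="ij")
        df = pd.DataFrame(
            {
                "env": np.asarray(env_order)[ii.ravel()],
                "line": np.asarray(line_order)[jj.ravel()],
                "rep": kk.ravel() + 1,
            }
        )
        df[list(trait_names)] = y.reshape(-1, L)
        df = df.dropna(subset=trait_names, how="all").reset_index(drop=True)
        return cls(df, list(env_order), list(line_order), list(trait_names))

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


@dataclass
class MarkerMatrix:
    """J x p biallelic marker dosages (0/1/2 internally), NaN for missing."""

    values: np.ndarray
    line_labels: list[str]
    marker_ids: list[str]
    kept: list[str] | None = None  # survivors of the last filtering pass

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("marker matrix must be 2-D")
        if self.values.shape[0] != len(self.line_labels):
            raise ValueError("marker row count does not match number of line labels")
        if self.values.shape[1] != len(self.marker_ids):
            raise ValueError("marker column count does not match number of marker ids")


@dataclass
class Grm:
    """Genomic relationship matrix among lines (symmetric PSD)."""

    matrix: np.ndarray
    line_labels: list[str]

    def __post_init__(self) -> None:
        G = np.asarray(self.matrix, dtype=float)
        if G.shape[0] != G.shape[1] or G.shape[0] != len(self.line_labels):
            raise ValueError("GRM must be square with one label per line")
        if not np.allclose(G, G.T, atol=1e-8 * max(1.0, np.abs(G).max())):
            raise ValueError("GRM is not symmetric")
        w = np.linalg.eigvalsh(G)
        if w[0] < -1e-8 * max(w[-1], 1.0):
            raise ValueError(f"GRM is not positive semi-definite (min eigenvalue {w[0]:.3g})")
        self.matrix = 0.5 * (G + G.T)

    def invertible_matrix(self, jitter_rel: float = 1e-6) -> np.ndarray:
        """Return Gg, jittered on the diagonal only if a Cholesky fails."""
        G = self.matrix
        try:
            np.linalg.cholesky(G)
            return G
        except np.linalg.LinAlgError:
            eps = jitter_rel * np.mean(np.diag(G))
            return G + eps * np.eye(G.shape[0])


@dataclass
class DesignMatrices:
    """Sparse incidence matrices of the stacked model Y = Xβ + Z1 b1 + Z2 b2 + e.

    X is (L·n)×(I·L) with β laid out trait-major (column l*I + i, 0-based);
    Z1 is (L·n)×(J·L) selecting line-by-trait effects (column j*L + l);
    Z2 is (L·n)×(I·J·L) selecting environment-by-line-by-trait effects.
    """

    X: sp.csr_matrix
    Z1: sp.csr_matrix
    Z2: sp.csr_matrix
    row_index: dict = field(repr=False)


# ---------------------------------------------------------------------------
# marker handling and the genomic relationship matrix


def encode_markers(
    raw: MarkerMatrix,
    maf_threshold: float = 0.05,
    max_missing_fraction: float = 0.8,
) -> MarkerMatrix:
    """Recode to 0/1/2 dosages, drop uninformative markers, impute the rest.

    Markers whose missing fraction exceeds ``max_missing_fraction`` or whose
    minor-allele frequency falls below ``maf_threshold`` are removed; remaining
    missing cells are replaced by the marker (column) mean.
    Accepts either the -1/0/1 or the 0/1/2 coding dialect.
    """
    if raw.values.shape[1] < 1:
        raise ValueError("marker matrix has no marker columns")
    for name, t in (("maf_threshold", maf_threshold), ("max_missing_fraction", max_missing_fraction)):
        if not (0.0 <= t < 1.0):
            raise ValueError(f"{name} must lie in [0, 1), got {t}")
    vals = raw.values.copy()
    finite = np.isfinite(vals)
    if np.nanmin(vals) < 0:  # -1/0/1 dialect
        vals = vals + 1.0
    if finite.any() and (np.nanmin(vals) < 0 or np.nanmax(vals) > 2):
        raise ValueError("marker codes must be -1/0/1 or 0/1/2")

    J = vals.shape[0]
    miss_frac = 1.0 - finite.sum(axis=0) / J
    with np.errstate(invalid="ignore"):
        p = np.nanmean(vals, axis=0) / 2.0
        spread = np.nanstd(vals, axis=0)
    maf = np.minimum(p, 1.0 - p)
    keep = (
        (miss_frac <= max_missing_fraction)
        & np.isfinite(maf)
        & (maf >= maf_threshold)
        & (maf > 0)
        & (spread > 0)  # a zero-variance column is monomorphic whatever its coding
    )
    if not keep.any():
        raise ValueError("no informative markers survive the MAF/missingness filters")
    vals = vals[:, keep]
    col_mean = np.nanmean(vals, axis=0)
    miss = ~np.isfinite(vals)
    vals[miss] = np.broadcast_to(col_mean, vals.shape)[miss]
    kept_ids = [m for m, k in zip(raw.marker_ids, keep) if k]
    return MarkerMatrix(vals, raw.line_labels, kept_ids, kept=kept_ids)


def compute_grm(markers: MarkerMatrix) -> Grm:
    """VanRaden genomic relationship matrix, G = W Wᵀ / (2 Σ p(1−p)).

    Columns of W are 0/1/2 dosages centered at twice the observed allele
    frequency.  Requires an imputed (complete) marker matrix with at least one
    polymorphic marker.
    """
    vals = markers.values
    if not np.isfinite(vals).all():
        raise ValueError("marker matrix still contains missing values; impute first")
    p = vals.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("no polymorphic markers: GRM denominator is zero")
    W = vals - 2.0 * p
    G = (W @ W.T) / denom
    return Grm(0.5 * (G + G.T), list(markers.line_labels))


# ---------------------------------------------------------------------------
# three-way arrangement and design matrices


def arrange_threeway(pheno: PhenotypeTable, dims: Dimensions) -> tuple[np.ndarray, np.ndarray]:
    """Stack the phenotype table into the canonical (L·n,) response vector.

    Returns ``(y, observed)``: missing cells hold NaN and ``observed`` is the
    boolean mask of non-missing entries.
    """
    if len(pheno.env_order) != dims.I or len(pheno.line_order) != dims.J or len(pheno.trait_names) != dims.L:
        raise ValueError("phenotype table factor orders are inconsistent with dims")
    y = pheno.to_arrays(dims).reshape(-1)
    return y, np.isfinite(y)


def arrange_inverse(
    y: np.ndarray,
    dims: Dimensions,
    env_order: list[str] | None = None,
    line_order: list[str] | None = None,
    trait_names: list[str] | None = None,
) -> PhenotypeTable:
    """Inverse of :func:`arrange_threeway` (records with all traits NaN are dropped)."""
    arr = np.asarray(y, dtype=float).reshape(dims.I, dims.J, dims.K, dims.L)
    return PhenotypeTable.from_arrays(arr, env_order, line_order, trait_names)


def build_design(dims: Dimensions, pheno: PhenotypeTable | None = None) -> DesignMatrices:
    """Incidence matrices for the full I×J×K×L grid in canonical row order."""
    if pheno is not None:
        if len(pheno.env_order) != dims.I or len(pheno.line_order) != dims.J or len(pheno.trait_names) != dims.L:
            raise ValueError("phenotype table factor orders are inconsistent with dims")
    I, J, K, L = dims.I, dims.J, dims.K, dims.L
    rows = np.arange(I * J * K * L)
    ii = rows // (J * K * L)
    jj = (rows // (K * L)) % J
    ll = rows % L
    ones = np.ones_like(rows, dtype=float)
    X = sp.csr_matrix((ones, (rows, ll * I + ii)), shape=(rows.size, I * L))
    Z1 = sp.csr_matrix((ones, (rows, jj * L + ll)), shape=(rows.size, J * L))
    Z2 = sp.csr_matrix((ones, (rows, (ii * J + jj) * L + ll)), shape=(rows.size, I * J * L))
    kk = (rows // L) % K
    row_index = {(int(i), int(j), int(k), int(l)): int(r) for r, (i, j, k, l) in enumerate(zip(ii, jj, kk, ll))}
    return DesignMatrices(X, Z1, Z2, row_index)


# ---------------------------------------------------------------------------
# plain-text readers (CSV/TSV)


def _read_rectangular(path, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited text file, rejecting ragged rows with the line number."""
    with open(path, "r", newline="") as fh:
        text = fh.read()
    if sep is None:
        sep = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=sep)
    rows = [r for r in reader if r]
    width = len(rows[0])
    for ln, r in enumerate(rows, start=1):
        if len(r) != width:
            raise ValueError(f"{path}: ragged row at line {ln} ({len(r)} fields, expected {width})")
    df = pd.read_csv(io.StringIO(text), sep=sep, na_values=["NA", ""])
    return df


def read_phenotypes(path, sep: str | None = None) -> PhenotypeTable:
    """Phenotype CSV/TSV with columns env,line,rep,<trait...> (missing = empty or NA)."""
    return PhenotypeTable.from_dataframe(_read_rectangular(path, sep))


def read_markers(path, sep: str | None = None) -> MarkerMatrix:
    """Marker CSV/TSV: first column line label, remaining columns marker dosages."""
    df = _read_rectangular(path, sep)
    labels = df.iloc[:, 0].astype(str).tolist()
    vals = df.iloc[:, 1:].to_numpy(dtype=float)
    return MarkerMatrix(vals, labels, [str(c) for c in df.columns[1:]])


def read_grm(path, sep: str | None = None) -> Grm:
    """Square GRM CSV with line labels in the first row and column."""
    df = _read_rectangular(path, sep)
    labels = df.iloc[:, 0].astype(str).tolist()
    G = df.iloc[:, 1:].to_numpy(dtype=float)
    cols = [str(c) for c in df.columns[1:]]
    if cols != labels:
        raise ValueError("GRM row and column labels disagree")
    return Grm(G, labels)
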