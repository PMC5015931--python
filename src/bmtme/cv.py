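"""Cross-validation plans, posterior prediction of masked cells, and metrics.

CV1 masks line-by-environment cells (all traits, all replicates): per fold,
each environment holds out 20% of the lines, under the constraint that no line
loses every environment — the situation of lines phenotyped in some
environments but missing in others.  CV2 masks one target trait in one whole
environment per fold (all lines, all replicates), the situation of a trait not
yet measured in a new environment.

Predicted values for masked cells are posterior means of the linear predictor
Xβ + Z1 b1 + Z2 b2; effects of held-out cells are drawn inside the chain,
shrunk through the genomic relationship matrix.  Accuracy is summarized per
environment-trait combination by the Pearson correlation and the mean squared
error of prediction (MSEP) across folds, and structures are compared by
tied-average ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import Dimensions, Grm, PhenotypeTable
from .distributions import HyperParams
from .sampler import McmcSettings, ModelData, StructureKind, run_chain

__all__ = [
    "CvPlan",
    "make_cv1_folds",
    "make_cv2_folds",
    "fit_predict",
    "score",
    "rank_models",
]


@dataclass
class CvPlan:
    """Per-fold boolean masks over the (I, J, K, L) grid; True = test cell."""

    scheme: str
    folds: list[np.ndarray]
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if self.scheme not in ("CV1", "CV2"):
            raise ValueError("scheme must be CV1 or CV2")
        if len(self.folds) != self.n_folds:
            raise ValueError("fold count does not match the fold list")


def make_cv1_folds(
    dims: Dimensions,
    pheno: PhenotypeTable,
    n_folds: int = 10,
    seed: int = 0,
    test_fraction: float = 0.2,
    by_line: bool = False,
    granularity: str = "cell",
) -> CvPlan:
    """CV1 folds: per fold and environment, ``test_fraction`` of the lines are
    masked for all replicates.

    ``granularity`` selects the masked unit: ``"cell"`` masks a line's whole
    line-by-environment cell (all traits), ``"trait"`` masks one trait of a
    line in one environment (its other traits stay observed, so prediction
    can also borrow through the trait covariances), and ``"line"``
    (equivalently ``by_line=True``) masks whole lines across every
    environment, leaving only kinship to predict from.

    The masked line groups of the environments (and traits, for ``"trait"``)
    within a fold are kept disjoint whenever capacity allows, so each tested
    line keeps I−1 observed environments — the incomplete-field-trial
    situation CV1 emulates.  When the groups can additionally tile the lines
    (n_folds × group size ≤ J) a single random partition is rotated and the
    folds then cover every maskable unit exactly once.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be at least 2")
    if by_line:
        granularity = "line"
    if granularity not in ("cell", "trait", "line"):
        raise ValueError("granularity must be 'cell', 'trait' or 'line'")
    if dims.I == 1 and granularity != "line":
        raise ValueError(
            "CV1 needs at least two environments so masked lines stay observed "
            "somewhere; with one environment use CV2 across traits or a plain holdout"
        )
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    J, I, L = dims.J, dims.I, dims.L
    n_test = max(1, round(test_fraction * J))
    folds: list[np.ndarray] = []

    if granularity == "line":
        if n_folds * n_test <= J:
            perm = rng.permutation(J)
            groups = [perm[f * n_test : (f + 1) * n_test] for f in range(n_folds)]
        else:
            groups = [rng.choice(J, size=n_test, replace=False) for _ in range(n_folds)]
        for f in range(n_folds):
            mask = np.zeros((I, J, dims.K, dims.L), dtype=bool)
            mask[:, groups[f], :, :] = True
            folds.append(mask)
        return CvPlan("CV1", folds, n_folds, seed)

    def fold_groups(n_units: int, offset) -> list[list[np.ndarray]]:
        """groups[u][f] = line indices masked for unit u (env, or env-trait)
        in fold f; a rotated partition when it fits, else per-fold disjoint
        permutation slices, else independent samples."""
        if n_folds * n_test <= J:
            perm = rng.permutation(J)
            parts = [perm[g * n_test : (g + 1) * n_test] for g in range(n_folds)]
            return [[parts[(f + offset(u)) % n_folds] for f in range(n_folds)] for u in range(n_units)]
        if n_units * n_test <= J:
            out: list[list[np.ndarray]] = [[None] * n_folds for _ in range(n_units)]
            for f in range(n_folds):
                perm = rng.permutation(J)
                for u in range(n_units):
                    out[u][f] = perm[u * n_test : (u + 1) * n_test]
            return out
        return [
            [rng.choice(J, size=n_test, replace=False) for _ in range(n_folds)] for _ in range(n_units)
        ]

    if granularity == "cell":
        env_groups = fold_groups(I, lambda i: i)
        for f in range(n_folds):
            sel = np.zeros((I, J), dtype=bool)
            for i in range(I):
                sel[i, env_groups[i][f]] = True
            # repair: a line masked in every environment swaps out of one of them
            for j in np.flatnonzero(sel.all(axis=0)):
                i = int(rng.integers(I))
                j2 = int(rng.choice(np.flatnonzero(~sel[i])))
                sel[i, j] = False
                sel[i, j2] = True
            mask = np.zeros((I, J, dims.K, dims.L), dtype=bool)
            mask[:, :, :, :] = sel[:, :, None, None]
            folds.append(mask)
        return CvPlan("CV1", folds, n_folds, seed)

    # granularity == "trait": units are environment-by-trait combinations;
    # the rotation offset i+l keeps a fold's masked line sets disjoint across
    # both environments and traits, so a masked line loses one trait in one
    # environment per (env, trait) hit
    unit_groups = fold_groups(I * L, lambda u: (u // L) + (u % L))
    for f in range(n_folds):
        sel = np.zeros((I, J, L), dtype=bool)
        for u in range(I * L):
            i, l = divmod(u, L)
            sel[i, unit_groups[u][f], l] = True
        # repair: keep at least one observed trait per cell (a partially
        # observed cell still counts as an observed environment for its line)
        for i, j in zip(*np.nonzero(sel.all(axis=2))):
            l = int(rng.integers(L))
            sel[i, j, l] = False
        mask = np.zeros((I, J, dims.K, dims.L), dtype=bool)
        mask[:, :, :, :] = sel[:, :, None, :]
        folds.append(mask)
    return CvPlan("CV1", folds, n_folds, seed)


def make_cv2_folds(dims: Dimensions, pheno: PhenotypeTable, trait: str, seed: int = 0) -> CvPlan:
    """CV2: one fold per environment, masking the target trait for all lines
    and replicates in that environment only."""
    if dims.I < 2:
        raise ValueError("CV2 needs at least two environments")
    if trait not in pheno.trait_names:
        raise ValueError(f"trait {trait!r} not in phenotype table {pheno.trait_names}")
    l = pheno.trait_names.index(trait)
    folds = []
    for i in range(dims.I):
        mask = np.zeros((dims.I, dims.J, dims.K, dims.L), dtype=bool)
        mask[i, :, :, l] = True
        folds.append(mask)
    return CvPlan("CV2", folds, dims.I, seed)


def fit_predict(
    pheno: PhenotypeTable,
    grm: Grm,
    hyper: HyperParams | None,
    kind: StructureKind,
    settings: McmcSettings,
    plan: CvPlan,
) -> pd.DataFrame:
    """Fit on each fold's training cells and predict its masked cells.

    Returns one row per masked, originally observed cell with columns
    ``fold, env, line, rep, trait, observed, predicted``.
    """
    dims = pheno.dims
    y_full = pheno.to_arrays(dims)
    rows = []
    for f, mask in enumerate(plan.folds):
        if mask.shape != y_full.shape:
            raise ValueError(f"fold {f} mask shape does not match the data")
        fold_seed = int(np.random.SeedSequence((settings.seed, 7, f)).generate_state(1)[0] % 2**31)
        try:
            samples = run_chain(
                ModelData.prepare(pheno, grm, hyper, dims=dims, train_mask=~mask),
                kind,
                replace(settings, seed=fold_seed),
            )
        except Exception as exc:
            raise RuntimeError(f"sampler failed on fold {f}: {exc}") from exc
        pred_cell = samples.predictor_mean()  # (I,J,L)
        test = mask & np.isfinite(y_full)
        ii, jj, kk, ll = np.nonzero(test)
        rows.append(
            pd.DataFrame(
                {
                    "fold": f,
                    "env": np.asarray(pheno.env_order)[ii],
                    "line": np.asarray(pheno.line_order)[jj],
                    "rep": kk + 1,
                    "trait": np.asarray(pheno.trait_names)[ll],
                    "observed": y_full[ii, jj, kk, ll],
                    "predicted": pred_cell[ii, jj, ll],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def score(predictions: pd.DataFrame) -> pd.DataFrame:
    """Fold-wise Pearson correlation and MSEP per environment-trait cell.

    Returns a long table with columns ``env, trait, criterion, mean, se``
    (SE = SD of fold values / √folds) plus an overall ``Ave`` row per
    criterion averaging the per-cell means.  A fold whose predictions have
    zero variance yields a missing correlation for that cell (warned, and
    excluded from the mean).
    """
    recs = []
    for (f, env, trait), g in predictions.groupby(["fold", "env", "trait"], sort=False):
        obs = g["observed"].to_numpy()
        pred = g["predicted"].to_numpy()
        msep = float(np.mean((obs - pred) ** 2))
        if len(obs) >= 2 and np.std(pred) > 0 and np.std(obs) > 0:
            corr = float(np.corrcoef(obs, pred)[0, 1])
        else:
            warnings.warn(
                f"zero-variance predictions in fold {f} for {env}-{trait}; correlation recorded as missing"
            )
            corr = np.nan
        recs.append((env, trait, f, corr, msep))
    per_fold = pd.DataFrame(recs, columns=["env", "trait", "fold", "correlation", "msep"])
    out = []
    for criterion in ("correlation", "msep"):
        g = per_fold.groupby(["env", "trait"], sort=False)[criterion]
        mean = g.mean()
        count = g.count()
        se = g.std(ddof=1) / np.sqrt(count)
        for (env, trait), m in mean.items():
            out.append((env, trait, criterion, m, se.loc[(env, trait)]))
        block = [r for r in out if r[2] == criterion]
        out.append(("Ave", "Ave", criterion, np.mean([r[3] for r in block]), np.mean([r[4] for r in block])))
    return pd.DataFrame(out, columns=["env", "trait", "criterion", "mean", "se"])


def rank_models(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Rank structures per environment-trait cell and criterion.

    Rank 1 is best: the highest correlation, the lowest MSEP.  Ties receive
    the average of the ranks they span.  An ``Ave`` row per structure and
    criterion holds its mean rank over the cells.
    """
    if len(tables) < 2:
        raise ValueError("need at least two structures to rank")
    frames = []
    keysets = []
    for name, tbl in tables.items():
        t = tbl[(tbl["env"] != "Ave")].copy()
        t["structure"] = name
        keysets.append(set(zip(t["env"], t["trait"], t["criterion"])))
        frames.append(t)
    if any(ks != keysets[0] for ks in keysets[1:]):
        raise ValueError("metric tables have mismatched (env, trait, criterion) keys")
    allt = pd.concat(frames, ignore_index=True)
    allt["rank"] = np.nan
    for (_, _, crit), group in allt.groupby(["env", "trait", "criterion"], sort=False):
        vals = -group["mean"] if crit == "correlation" else group["mean"]
        allt.loc[group.index, "rank"] = vals.rank(method="average").to_numpy()
    ave = (
        allt.groupby(["structure", "criterion"], sort=False)["rank"]
        .mean()
        .reset_index()
        .assign(env="Ave", trait="Ave", mean=np.nan, se=np.nan)
    )
    return pd.concat([allt, ave], ignore_index=True)[
        ["structure", "env", "trait", "criterion", "mean", "se", "rank"]
    ]
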