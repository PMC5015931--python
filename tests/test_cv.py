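"""Cross-validation plans, scoring and model ranking."""

import numpy as np
import pandas as pd
import pytest

from bmtme import (
    Dimensions,
    Grm,
    McmcSettings,
    PhenotypeTable,
    StructureKind,
    build_design,
    fit_predict,
    make_cv1_folds,
    make_cv2_folds,
    rank_models,
    score,
)


@pytest.fixture
def sim_pheno():
    rng = np.random.default_rng(77)
    return PhenotypeTable.from_arrays(rng.normal(10, 1, size=(3, 80, 2, 3)))


class TestCv1Folds:
    def test_each_fold_masks_20_percent_of_cells(self, sim_pheno):
        dims = sim_pheno.dims
        plan = make_cv1_folds(dims, sim_pheno, n_folds=10, seed=1)
        for mask in plan.folds:
            cells = mask[:, :, 0, 0]
            assert cells.sum() == 48  # 20% of the 240 line-environment cells
            assert mask.sum() == 48 * dims.K * dims.L  # all traits, all replicates

    def test_masked_lines_keep_one_environment(self, sim_pheno):
        plan = make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=10, seed=2)
        for mask in plan.folds:
            cells = mask[:, :, 0, 0]
            assert not cells.all(axis=0).any()

    def test_five_folds_partition_the_cells(self, sim_pheno):
        plan = make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=5, seed=3)
        total = np.zeros_like(plan.folds[0], dtype=int)
        for mask in plan.folds:
            total += mask
        np.testing.assert_array_equal(total, 1)  # every cell tested exactly once

    def test_trait_granularity_masks_one_trait_per_cell(self, sim_pheno):
        plan = make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=5, seed=4, granularity="trait")
        for mask in plan.folds:
            cells = mask[:, :, 0, :]  # (I,J,L)
            per_env_trait = cells.sum(axis=1)
            np.testing.assert_array_equal(per_env_trait, 16)  # 20% of lines per env-trait
            assert not cells.all(axis=2).any()  # never all traits of a cell

    def test_by_line_masks_whole_lines(self, sim_pheno):
        plan = make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=5, seed=5, by_line=True)
        for mask in plan.folds:
            lines = mask.any(axis=(0, 2, 3))
            assert lines.sum() == 16
            np.testing.assert_array_equal(mask[:, lines], True)

    def test_deterministic_given_seed(self, sim_pheno):
        p1 = make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=4, seed=9)
        p2 = make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=4, seed=9)
        for a, b in zip(p1.folds, p2.folds):
            np.testing.assert_array_equal(a, b)

    def test_single_environment_directs_to_cv2(self):
        pheno = PhenotypeTable.from_arrays(np.random.default_rng(0).normal(size=(1, 10, 2, 2)))
        with pytest.raises(ValueError, match="CV2"):
            make_cv1_folds(pheno.dims, pheno, n_folds=5)

    def test_too_few_folds_rejected(self, sim_pheno):
        with pytest.raises(ValueError, match="n_folds"):
            make_cv1_folds(sim_pheno.dims, sim_pheno, n_folds=1)


class TestCv2Folds:
    def test_one_fold_per_environment_target_trait_only(self, sim_pheno):
        dims = sim_pheno.dims
        plan = make_cv2_folds(dims, sim_pheno, trait="T2")
        assert plan.n_folds == dims.I
        for i, mask in enumerate(plan.folds):
            assert mask.sum() == dims.J * dims.K  # all lines and replicates, one trait
            assert mask[i, :, :, 1].all()
            assert not mask[:, :, :, [0, 2]].any()  # non-target traits never masked
            others = [j for j in range(dims.I) if j != i]
            assert not mask[others].any()

    def test_unknown_trait_rejected(self, sim_pheno):
        with pytest.raises(ValueError, match="trait"):
            make_cv2_folds(sim_pheno.dims, sim_pheno, trait="Yield")

    def test_needs_two_environments(self):
        pheno = PhenotypeTable.from_arrays(np.random.default_rng(0).normal(size=(1, 4, 1, 2)))
        with pytest.raises(ValueError, match="environments"):
            make_cv2_folds(pheno.dims, pheno, trait="T1")


def metric_frame(rows):
    return pd.DataFrame(rows, columns=["env", "trait", "criterion", "mean", "se"])


class TestScore:
    def make_preds(self, obs, pred, env="E1", trait="T1", fold=0):
        n = len(obs)
        return pd.DataFrame(
            {"fold": fold, "env": env, "line": [f"L{i}" for i in range(n)], "rep": 1,
             "trait": trait, "observed": obs, "predicted": pred}
        )

    def test_perfect_predictions(self):
        tbl = score(self.make_preds([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        row = tbl[(tbl.env == "E1") & (tbl.criterion == "correlation")]
        assert row["mean"].iloc[0] == pytest.approx(1.0)
        row = tbl[(tbl.env == "E1") & (tbl.criterion == "msep")]
        assert row["mean"].iloc[0] == pytest.approx(0.0)

    def test_constant_predictions_hand_example(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            tbl = score(self.make_preds([1.0, 2.0, 3.0], [2.0, 2.0, 2.0]))
        msep = tbl[(tbl.criterion == "msep") & (tbl.env == "E1")]["mean"].iloc[0]
        assert msep == pytest.approx(2.0 / 3.0)
        corr = tbl[(tbl.criterion == "correlation") & (tbl.env == "E1")]["mean"].iloc[0]
        assert np.isnan(corr)

    def test_invariant_to_cell_order(self, rng):
        preds = self.make_preds(rng.normal(size=8), rng.normal(size=8))
        shuffled = preds.sample(frac=1.0, random_state=1)
        pd.testing.assert_frame_equal(
            score(preds).reset_index(drop=True), score(shuffled).reset_index(drop=True)
        )

    def test_mean_and_se_across_folds(self):
        preds = pd.concat(
            [self.make_preds([1.0, 2.0, 4.0], [1.0, 2.0, 3.0], fold=f) for f in range(2)]
            + [self.make_preds([1.0, 2.0, 4.0], [1.5, 2.0, 3.0], fold=2)]
        )
        tbl = score(preds)
        msep = tbl[(tbl.criterion == "msep") & (tbl.env == "E1")]
        folds = np.array([1 / 3, 1 / 3, (0.25 + 1) / 3])
        assert msep["mean"].iloc[0] == pytest.approx(folds.mean())
        assert msep["se"].iloc[0] == pytest.approx(folds.std(ddof=1) / np.sqrt(3))


class TestRankModels:
    def make_tables(self, corrs, mseps):
        out = {}
        for name, c, m in zip(["U", "D", "S"], corrs, mseps):
            out[name] = metric_frame(
                [("E1", "T1", "correlation", c, 0.01), ("E1", "T1", "msep", m, 0.01)]
            )
        return out

    def test_tied_correlations_get_average_ranks(self):
        ranks = rank_models(self.make_tables([0.40, 0.40, 0.39], [1.0, 1.1, 1.2]))
        r = ranks[(ranks.criterion == "correlation") & (ranks.env == "E1")]
        assert sorted(r["rank"]) == [1.5, 1.5, 3.0]

    def test_distinct_values_give_permutation(self):
        ranks = rank_models(self.make_tables([0.5, 0.3, 0.4], [1.0, 1.2, 1.1]))
        r = ranks[(ranks.criterion == "msep") & (ranks.env == "E1")]
        assert sorted(r["rank"]) == [1.0, 2.0, 3.0]

    def test_criterion_direction(self):
        # the same numbers rank oppositely under correlation (higher wins)
        # and msep (lower wins)
        ranks = rank_models(self.make_tables([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]))
        r = ranks[ranks.env == "E1"].pivot(index="structure", columns="criterion", values="rank")
        assert (r["correlation"] + r["msep"] == 4.0).all()

    def test_rank_sum_property(self):
        ranks = rank_models(self.make_tables([0.4, 0.4, 0.4], [1.0, 1.0, 2.0]))
        for _, grp in ranks[ranks.env == "E1"].groupby("criterion"):
            assert grp["rank"].sum() == pytest.approx(6.0)  # S(S+1)/2 with S=3

    def test_mismatched_keys_rejected(self):
        tables = self.make_tables([0.4, 0.5, 0.6], [1.0, 1.0, 1.0])
        tables["D"] = tables["D"].assign(env="E9")
        with pytest.raises(ValueError, match="mismatched"):
            rank_models(tables)


class TestFitPredict:
    def test_linear_predictor_consistent_with_design_matrices(self):
        """Posterior-mean predictions equal the design-matrix linear predictor
        evaluated at posterior means (averaging commutes by linearity)."""
        rng = np.random.default_rng(3)
        pheno = PhenotypeTable.from_arrays(rng.normal(5, 1, size=(2, 4, 2, 2)))
        dims = pheno.dims
        grm = Grm(0.5 * np.eye(4) + 0.5 * np.ones((4, 4)), pheno.line_order)
        mask = np.zeros((2, 4, 2, 2), dtype=bool)
        mask[0, 0] = True
        from bmtme.cv import CvPlan

        plan = CvPlan("CV1", [mask], 1, 0)
        settings = McmcSettings(iterations=200, burn_in=100, seed=8)
        preds = fit_predict(pheno, grm, None, StructureKind.UNSTRUCTURED, settings, plan)

        from bmtme.sampler import ModelData, run_chain

        samples = run_chain(
            ModelData.prepare(pheno, grm, None, train_mask=~mask),
            StructureKind.UNSTRUCTURED,
            McmcSettings(
                iterations=200, burn_in=100,
                seed=int(np.random.SeedSequence((8, 7, 0)).generate_state(1)[0] % 2**31),
            ),
        )
        dm = build_design(dims)
        beta_flat = samples.beta.mean(axis=0).T.ravel()  # trait-major
        lin = dm.X @ beta_flat + dm.Z1 @ samples.b1.mean(axis=0).ravel() + dm.Z2 @ samples.b2.mean(axis=0).ravel()
        for _, row in preds.iterrows():
            i = pheno.env_order.index(row.env)
            j = pheno.line_order.index(row.line)
            l = pheno.trait_names.index(row.trait)
            r = dm.row_index[(i, j, int(row.rep) - 1, l)]
            assert row.predicted == pytest.approx(lin[r])

    def test_predictions_only_for_masked_observed_cells(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(2, 4, 1, 2))
        y[0, 1, 0, 0] = np.nan  # already missing: never scored
        pheno = PhenotypeTable.from_arrays(y)
        grm = Grm(np.eye(4), pheno.line_order)
        mask = np.zeros_like(np.isfinite(y))
        mask[0, :2] = True
        from bmtme.cv import CvPlan

        preds = fit_predict(
            pheno, grm, None, StructureKind.UNSTRUCTURED,
            McmcSettings(iterations=60, burn_in=20, seed=1), CvPlan("CV1", [mask], 1, 0),
        )
        assert len(preds) == 3  # 2 cells x 2 traits minus the missing one
        assert not ((preds.env == "E1") & (preds.line == "L2") & (preds.trait == "T1")).any()
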