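"""Profiled-REML mixed models: oracles, calibration, mass-fit contracts."""

import numpy as np
import pandas as pd
import pytest

import painconn as pc
from painconn import lmm
from painconn.lmm import MassSlopeEngine, _fit_scalar

from conftest import make_grouped_data


class TestScalarFitter:
    def test_ols_limit_when_group_variance_zero(self):
        # within-group demeaned outcome forces the variance ratio to the
        # boundary, where the fit must equal closed-form OLS
        rng = np.random.default_rng(10)
        df = make_grouped_data(rng, group_sd=1.0)
        y = df["rating"].to_numpy()
        g = df["subject"].to_numpy()
        for group in np.unique(g):
            y[g == group] -= y[g == group].mean()
        df["rating"] = y + y.mean()
        fit = pc.fit_random_intercept(df, standardize=False)
        assert fit.sigma2_group == 0.0
        X = np.column_stack([np.ones(len(df)), df["z"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["rating"].to_numpy())
        resid = df["rating"].to_numpy() - X @ beta
        sigma2 = resid @ resid / (len(df) - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X).diagonal())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-6)
        np.testing.assert_allclose(fit.se.to_numpy(), se, rtol=1e-6)

    def test_matches_lme4_cross_implementation(self):
        from conftest import lme4_tstats

        rng = np.random.default_rng(11)
        frames = [
            make_grouped_data(
                rng,
                n_groups=int(rng.integers(8, 14)),
                per_group=int(rng.integers(10, 20)),
                slope=float(rng.normal(0, 2)),
                group_sd=float(rng.uniform(1.5, 3.0)),
                noise_sd=float(rng.uniform(0.8, 1.5)),
            )
            for _ in range(8)
        ]
        oracle = lme4_tstats(frames)
        for df, t_ref in zip(frames, oracle):
            fit = pc.fit_random_intercept(df, standardize=False)
            np.testing.assert_allclose(fit.tstat.to_numpy(), t_ref, atol=1e-4)

    def test_statsmodels_agrees_within_its_optimizer_precision(self):
        # second cross-implementation check; statsmodels' MixedLM optimizers
        # converge more loosely than the profiled 1-D search, so the
        # comparison tolerance reflects their convergence, not ours
        import warnings

        import statsmodels.formula.api as smf

        rng = np.random.default_rng(21)
        for _ in range(4):
            df = make_grouped_data(
                rng, n_groups=12, per_group=15, slope=1.0,
                group_sd=2.0, noise_sd=1.0,
            )
            fit = pc.fit_random_intercept(df, standardize=False)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm = smf.mixedlm(
                    "rating ~ z", df, groups=df["subject"]
                ).fit(reml=True)
            t_sm = (sm.params[:2] / sm.bse[:2]).to_numpy()
            np.testing.assert_allclose(fit.tstat.to_numpy(), t_sm, atol=5e-2)

    def test_variance_components_nonnegative_random_datasets(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            df = make_grouped_data(
                rng,
                n_groups=int(rng.integers(4, 8)),
                per_group=int(rng.integers(4, 10)),
                slope=0.0,
                group_sd=float(rng.uniform(0.0, 2.0)),
            )
            fit = pc.fit_random_intercept(df, standardize=False)
            assert fit.sigma2_group >= 0.0
            assert fit.sigma2_resid > 0.0
            assert np.isfinite(fit.tstat).all()

    def test_type_one_error_calibrated(self):
        # zero slope truth, balanced two-group toy, 1000 replicates
        rng = np.random.default_rng(13)
        n_per, n_rep = 30, 1000
        subj = np.repeat(["a", "b"], n_per)
        x = rng.standard_normal(2 * n_per)
        Y = (
            np.repeat(rng.normal(0, 2, (2, n_rep)), n_per, axis=0)
            + rng.standard_normal((2 * n_per, n_rep))
        )
        engine = MassSlopeEngine(x, subj)
        t = engine.fit(Y)["tstat"][0]
        rate = float(np.mean(np.abs(t) > 1.96))
        assert 0.03 <= rate <= 0.07
        assert abs(engine.fit(Y)["beta"][0].mean()) < 0.02

    def test_constant_predictor_rejected(self):
        df = make_grouped_data(np.random.default_rng(1))
        df["z"] = 1.0
        with pytest.raises(ValueError, match="constant predictor"):
            pc.fit_random_intercept(df)


class TestBatchEngine:
    def test_batch_equals_scalar_path(self):
        rng = np.random.default_rng(14)
        n_groups, per_group = 9, 11
        subj = np.repeat(np.arange(n_groups), per_group)
        X = rng.standard_normal((n_groups * per_group, 4))
        Y = rng.standard_normal((n_groups * per_group, 3)) + np.repeat(
            rng.normal(0, 1.5, (n_groups, 3)), per_group, axis=0
        )
        out = MassSlopeEngine(X, subj).fit(Y)
        for e in range(4):
            for p in range(3):
                res = _fit_scalar(
                    Y[:, p],
                    np.column_stack([np.ones(len(subj)), X[:, e]]),
                    subj,
                )
                assert out["tstat"][e, p] == pytest.approx(
                    res["tstat"][1], abs=1e-5
                )
                assert out["beta"][e, p] == pytest.approx(
                    res["beta"][1], abs=1e-6
                )

    def test_unbalanced_groups_supported(self):
        rng = np.random.default_rng(15)
        sizes = [5, 9, 13, 7, 16]
        subj = np.concatenate([[i] * s for i, s in enumerate(sizes)])
        x = rng.standard_normal(len(subj))
        y = 1.0 + 0.4 * x + np.concatenate(
            [[rng.normal(0, 1.2)] * s for s in sizes]
        ) + rng.standard_normal(len(subj))
        out = MassSlopeEngine(x, subj).fit(y)
        res = _fit_scalar(y, np.column_stack([np.ones(len(subj)), x]), subj)
        assert out["tstat"][0, 0] == pytest.approx(res["tstat"][1], abs=1e-5)


class TestInteractionModel:
    @staticmethod
    def _two_condition_data(rng, slope_a=0.0, slope_b=-8.0, n_subj=14, n_trial=10):
        rows = []
        for s in range(n_subj):
            for cond, slope in (("unmod", slope_a), ("task", slope_b)):
                a = rng.normal(0, 6)
                z = rng.standard_normal(n_trial)
                for t in range(n_trial):
                    rows.append(
                        (f"s{s}", cond, t, z[t],
                         50 + a + slope * z[t] + rng.normal(0, 5))
                    )
        return pd.DataFrame(
            rows, columns=["subject", "condition", "trial", "z", "rating"]
        )

    def test_interaction_recovers_slope_contrast(self):
        rng = np.random.default_rng(16)
        df = self._two_condition_data(rng)
        fit = pc.fit_condition_interaction(df, standardize=False)
        est = float(fit.params["z:cond[task]"])
        se = float(fit.se["z:cond[task]"])
        assert abs(est - (-8.0)) < 2 * se

    def test_equal_slopes_interaction_near_zero(self):
        rng = np.random.default_rng(17)
        ts = []
        for _ in range(10):
            df = self._two_condition_data(rng, slope_a=-4.0, slope_b=-4.0)
            fit = pc.fit_condition_interaction(df, standardize=False)
            ts.append(float(fit.tstat["z:cond[task]"]))
        assert abs(np.mean(ts)) < 1.0

    def test_single_subject_condition_rejected(self):
        rng = np.random.default_rng(18)
        df = self._two_condition_data(rng, n_subj=4)
        df = df[~((df["condition"] == "task") & (df["subject"] != "s0"))]
        with pytest.raises(ValueError, match="fewer than 2 subjects"):
            pc.fit_condition_interaction(df)


class TestMediationModel:
    def test_constant_structural_weights_rejected(self):
        df = make_grouped_data(np.random.default_rng(19))
        df["struc"] = 7.0
        with pytest.raises(ValueError, match="constant"):
            pc.fit_structural_mediation(df)

    def test_permuting_structural_weights_destroys_effect(self, planted_sim,
                                                          planted_tensor):
        k = planted_tensor.edge_index.index_of("r003", "r004")
        rows = lmm.select_condition_rows(
            planted_tensor.trials, "counting", "unmodulated"
        )
        df = planted_tensor.trials.loc[rows, ["subject", "rating"]].copy()
        df["z"] = planted_tensor.z[rows, k]
        counts = {
            s: planted_sim.structural_matrix[s][2, 3] for s in planted_sim.subjects
        }
        df["struc"] = df["subject"].map(
            {s: np.log1p(c) for s, c in counts.items()}
        )
        t_true = abs(float(pc.fit_structural_mediation(df).tstat["z:struc"]))
        assert t_true > 2.0
        rng = np.random.default_rng(20)
        t_perm = []
        subjects = list(counts)
        for _ in range(20):
            perm = rng.permutation(len(subjects))
            mapping = {
                subjects[i]: np.log1p(counts[subjects[perm[i]]])
                for i in range(len(subjects))
            }
            dfp = df.copy()
            dfp["struc"] = dfp["subject"].map(mapping)
            t_perm.append(abs(float(pc.fit_structural_mediation(dfp).tstat["z:struc"])))
        assert np.mean(t_perm) < 1.5


class TestMassFit:
    def test_counts_and_alignment(self, planted_tensor):
        stats_df = lmm.mass_fit(planted_tensor, model="M1", condition="counting")
        assert len(stats_df) == planted_tensor.edge_index.n_edges
        pd.testing.assert_frame_equal(
            stats_df[["region_a", "region_b"]],
            planted_tensor.edge_index.to_frame(),
        )

    def test_per_edge_equals_standalone_fit(self, planted_tensor):
        stats_df = lmm.mass_fit(planted_tensor, model="M1", condition="counting")
        rows = lmm.select_condition_rows(
            planted_tensor.trials, "counting", "unmodulated"
        )
        for k in (0, 5, 17):
            df = planted_tensor.trials.loc[rows, ["subject", "rating"]].copy()
            df["z"] = planted_tensor.z[rows, k]
            fit = pc.fit_random_intercept(df)
            assert float(stats_df.loc[k, "t"]) == pytest.approx(
                float(fit.tstat["z"]), abs=1e-5
            )

    def test_skipped_edges_marked_not_numeric(self, planted_tensor):
        import dataclasses

        z = planted_tensor.z.copy()
        z[: int(0.5 * z.shape[0]), 3] = np.nan      # 50% missing -> skip
        broken = dataclasses.replace(planted_tensor, z=z)
        stats_df = lmm.mass_fit(broken, model="M1", condition="counting")
        assert bool(stats_df.loc[3, "skipped"])
        assert np.isnan(stats_df.loc[3, "t"])

    def test_missing_unmodulated_condition_rejected(self, planted_tensor):
        import dataclasses

        trials = planted_tensor.trials.copy()
        trials["condition"] = "counting"
        broken = dataclasses.replace(planted_tensor, trials=trials)
        with pytest.raises(ValueError, match="unmodulated"):
            lmm.mass_fit(
                broken, model="M1", condition="counting", unmodulated="unmodulated"
            )

    def test_prefilter_threshold_semantics(self, planted_tensor):
        stats_df = lmm.mass_fit(planted_tensor, model="M1", condition="counting")
        subset = lmm.prefilter_for_mediation(stats_df, threshold=2.0)
        assert (subset["t"].abs() > 2.0).all()
        everything = lmm.prefilter_for_mediation(stats_df, threshold=0.0)
        assert len(everything) == (~stats_df["skipped"]).sum()
        high = lmm.prefilter_for_mediation(stats_df, threshold=1e9)
        assert high.empty
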