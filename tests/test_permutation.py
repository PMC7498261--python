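"""Rating shuffles, max-|t| null distributions, corrected p-values."""

import numpy as np
import pandas as pd
import pytest

import painconn as pc
from painconn.permutation import NullDistribution


@pytest.fixture(scope="module")
def null_dist(planted_tensor):
    return pc.build_null(
        planted_tensor, model="M1", condition="counting",
        n_perms=200, seed=101,
    )


class TestPermuteRatings:
    def test_multiset_preserved_per_subject(self, planted_sim):
        trials = planted_sim.trial_table
        shuffled = pc.permute_ratings(trials, seed=1)
        for subject, sub in trials.groupby("subject"):
            assert sorted(sub["rating"]) == sorted(
                shuffled.loc[shuffled["subject"] == subject, "rating"]
            )
        for col in ("subject", "condition", "trial", "onset_sample"):
            assert trials[col].equals(shuffled[col])

    def test_seed_reproducible(self, planted_sim):
        a = pc.permute_ratings(planted_sim.trial_table, seed=7)
        b = pc.permute_ratings(planted_sim.trial_table, seed=7)
        assert a["rating"].equals(b["rating"])

    def test_two_trials_both_arrangements_equally_likely(self):
        trials = pd.DataFrame(
            {
                "subject": ["a", "a", "b", "b"],
                "condition": ["u", "c", "u", "c"],
                "trial": [0, 0, 0, 0],
                "onset_sample": [5, 30, 5, 30],
                "rating": [10.0, 20.0, 30.0, 40.0],
            }
        )
        n_flip = 0
        n_draws = 4000
        for s in range(n_draws):
            out = pc.permute_ratings(trials, seed=s)
            n_flip += out["rating"].iloc[0] == 20.0
        # exhaustive enumeration: 2 arrangements per subject, each ~50%
        assert 0.45 < n_flip / n_draws < 0.55

    def test_fewer_than_two_trials_rejected(self):
        trials = pd.DataFrame(
            {"subject": ["a"], "condition": ["u"], "trial": [0],
             "onset_sample": [0], "rating": [5.0]}
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            pc.permute_ratings(trials)


class TestBuildNull:
    def test_default_repetition_count_is_5000(self):
        from painconn.permutation import DEFAULT_N_PERMS
        import inspect

        assert DEFAULT_N_PERMS == 5000
        sig = inspect.signature(pc.build_null)
        assert sig.parameters["n_perms"].default == 5000

    def test_deterministic_and_worker_count_independent(self, planted_tensor):
        kwargs = dict(
            model="M1", condition="counting", n_perms=40, seed=11, chunk_size=7
        )
        a = pc.build_null(planted_tensor, n_jobs=1, **kwargs)
        b = pc.build_null(planted_tensor, n_jobs=2, **kwargs)
        np.testing.assert_array_equal(a.max_abs_t, b.max_abs_t)
        c = pc.build_null(
            planted_tensor, model="M1", condition="counting",
            n_perms=40, seed=11, chunk_size=40,
        )
        np.testing.assert_array_equal(a.max_abs_t, c.max_abs_t)

    def test_zero_permutations_rejected(self, planted_tensor):
        with pytest.raises(ValueError, match="n_perms"):
            pc.build_null(
                planted_tensor, model="M1", condition="counting", n_perms=0
            )

    def test_null_values_finite_nonnegative(self, null_dist):
        assert np.isfinite(null_dist.max_abs_t).all()
        assert (null_dist.max_abs_t >= 0).all()
        assert null_dist.n_edges_fitted == 28


class TestCorrectedPvalues:
    @staticmethod
    def _stats_frame(ts):
        n = len(ts)
        return pd.DataFrame(
            {
                "region_a": [f"r{i}" for i in range(n)],
                "region_b": [f"q{i}" for i in range(n)],
                "beta": -np.asarray(ts, dtype=float),
                "se": np.ones(n),
                "t": np.asarray(ts, dtype=float),
                "skipped": [False] * n,
                "attenuation_encoding": [t < 0 for t in ts],
            }
        )

    @staticmethod
    def _null(values, seed=0):
        return NullDistribution(
            condition="c", model="M1",
            max_abs_t=np.asarray(values, dtype=float),
            n_perms=len(values), seed=seed,
        )

    def test_extreme_observation_gets_smallest_pvalue(self):
        null = self._null(np.linspace(0.5, 3.0, 99))
        rep = pc.corrected_pvalues(self._stats_frame([10.0]), null)
        assert rep.edges["p_corrected"].iloc[0] == pytest.approx(1.0 / 100.0)

    def test_zero_statistic_gets_pvalue_one(self):
        null = self._null(np.linspace(0.5, 3.0, 99))
        rep = pc.corrected_pvalues(self._stats_frame([0.0]), null)
        assert rep.edges["p_corrected"].iloc[0] == pytest.approx(1.0)

    def test_flag_threshold_pvalue_consistency(self):
        rng = np.random.default_rng(23)
        null = self._null(rng.chisquare(3, 199))
        ts = rng.normal(0, 3, 50)
        rep = pc.corrected_pvalues(self._stats_frame(ts), null, alpha=0.05)
        flags = rep.edges["significant"].to_numpy()
        np.testing.assert_array_equal(
            flags, rep.edges["p_corrected"].to_numpy() <= 0.05
        )
        np.testing.assert_array_equal(
            flags, np.abs(ts) > rep.threshold_t
        )

    def test_family_wise_error_rate_small_sim(self):
        # 10 independent edges under the global null, alpha 0.05:
        # the chance that any edge is flagged should sit near alpha
        rng = np.random.default_rng(24)
        n_rep, n_perm, n_edges = 400, 199, 10
        fp = 0
        for _ in range(n_rep):
            null_vals = np.abs(rng.standard_normal((n_perm, n_edges))).max(axis=1)
            obs = np.abs(rng.standard_normal(n_edges))
            null = self._null(null_vals)
            rep = pc.corrected_pvalues(self._stats_frame(obs), null)
            fp += bool(rep.edges["significant"].any())
        assert 0.03 <= fp / n_rep <= 0.07


class TestNullShape:
    def test_right_skewed(self, null_dist):
        assert null_dist.skewness() > 0.0

    def test_observed_max_within_null_band_under_global_null(self, small_null_sim):
        # calibration: the observed max |t| of a null dataset is an ordinary
        # draw from its own permutation null distribution
        tensor = pc.tensor_from_simulation(small_null_sim)
        inside = 0
        for rep in range(12):
            sim = pc.simulate_dataset(
                pc.SimConfig(
                    n_subjects=8, n_regions=6,
                    conditions=("unmodulated", "counting"),
                    trials_per_condition=8, seed=500 + rep,
                )
            )
            tensor = pc.tensor_from_simulation(sim)
            from painconn import lmm

            stats_df = lmm.mass_fit(tensor, model="M1", condition="counting")
            null = pc.build_null(
                tensor, model="M1", condition="counting",
                n_perms=100, seed=600 + rep,
            )
            obs = np.nanmax(np.abs(stats_df["t"].to_numpy(dtype=float)))
            lo, hi = np.quantile(null.max_abs_t, [0.025, 0.975])
            inside += bool(lo <= obs <= hi)
        assert inside >= 9  # ~95% coverage, binomial slack at 12 replicates
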