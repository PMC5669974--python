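"""Hypercube sampling, tail conditioning and MIRI estimators."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest, norm

from rppacra.robustness import (
    InsufficientDataError,
    ParameterSpace,
    SampleSet,
    TailSpec,
    compute_miri,
    miri_matrix,
    sample_hypercube,
    select_joint_tail,
)


def space_1d(bounds=(-1.0, 1.0)):
    return ParameterSpace(names=["k"], nominal=np.array([1.0]),
                          log10_bounds=bounds)


class TestHypercube:
    def test_each_log_stratum_hit_once(self):
        """n=10 over a two-decade box: one draw per log-decade cell."""
        draws = sample_hypercube(space_1d(), 10, seed=0)
        strata = np.floor((np.log10(draws["k"]) + 1.0) / 0.2).astype(int)
        assert sorted(strata) == list(range(10))

    def test_same_seed_same_draws(self):
        a = sample_hypercube(space_1d(), 50, seed=7)
        b = sample_hypercube(space_1d(), 50, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_marginal_is_log_uniform(self):
        draws = sample_hypercube(space_1d(), 10_000, seed=3)
        stat = kstest(np.log10(draws["k"]), "uniform", args=(-1.0, 2.0))
        assert stat.pvalue > 0.01

    def test_fixed_dimensions_are_constant(self):
        space = ParameterSpace(
            names=["a", "b"], nominal=np.array([1.0, 2.0]), fixed={"b": 3.0}
        )
        draws = sample_hypercube(space, 20, seed=1)
        assert (draws["b"] == 3.0).all()
        assert draws["a"].nunique() == 20

    def test_argument_errors(self):
        with pytest.raises(ValueError):
            sample_hypercube(space_1d(), 1, seed=0)
        space = ParameterSpace(names=["a"], nominal=np.array([1.0]),
                               fixed={"a": 1.0})
        with pytest.raises(ValueError, match="degenerate"):
            sample_hypercube(space, 10, seed=0)


def synthetic_samples(eval_frame: pd.DataFrame, seed: int = 0) -> SampleSet:
    n = len(eval_frame)
    draws = pd.DataFrame({"p": np.arange(n, dtype=float) + 1.0})
    return SampleSet(draws=draws, eval_values=eval_frame,
                     failed=np.zeros(n, dtype=bool), seed=seed)


class TestJointTail:
    def test_single_protein_alpha_tails(self, rng):
        samples = synthetic_samples(pd.DataFrame({"A": rng.normal(size=100)}))
        s_idx, l_idx, fallback = select_joint_tail(
            samples, TailSpec(alpha=0.1, directions={"A": "upper"})
        )
        assert not fallback
        assert len(s_idx) == 10 and len(l_idx) == 10
        vals = samples.eval_values["A"].to_numpy()
        assert vals[s_idx].min() > np.percentile(vals, 85)
        assert vals[l_idx].max() < np.percentile(vals, 15)

    def test_perfectly_correlated_proteins_reduce_to_single_tails(self, rng):
        x = rng.normal(size=200)
        samples = synthetic_samples(pd.DataFrame({"A": x, "B": 2 * x + 1}))
        spec = TailSpec(alpha=0.1, directions={"A": "upper", "B": "upper"})
        s_idx, l_idx, fallback = select_joint_tail(samples, spec)
        single, _, _ = select_joint_tail(
            samples, TailSpec(alpha=0.1, directions={"A": "upper"})
        )
        assert not fallback
        assert np.array_equal(s_idx, single)

    def test_independent_proteins_intersect_like_alpha_squared(self, rng):
        n = 100_000
        frame = pd.DataFrame({"A": rng.normal(size=n), "B": rng.normal(size=n)})
        spec = TailSpec(alpha=0.1, directions={"A": "upper", "B": "upper"})
        s_idx, l_idx, fallback = select_joint_tail(synthetic_samples(frame), spec)
        assert not fallback
        # product law: alpha^2 * n = 1000; allow ~4 sigma of binomial noise
        assert abs(len(s_idx) - 1000) < 130
        assert abs(len(l_idx) - 1000) < 130

    def test_opposite_direction_protein_flips_its_tail(self, rng):
        x = rng.normal(size=400)
        samples = synthetic_samples(pd.DataFrame({"A": x, "B": -x}))
        spec = TailSpec(alpha=0.1, directions={"A": "upper", "B": "lower"})
        s_idx, _, fallback = select_joint_tail(samples, spec)
        assert not fallback
        assert samples.eval_values["A"].to_numpy()[s_idx].min() > 0

    def test_alpha_validation(self):
        with pytest.raises(ValueError):
            TailSpec(alpha=0.6)
        with pytest.raises(ValueError):
            TailSpec(alpha=0.1, directions={"A": "sideways"})


class TestMiri:
    def test_identical_sets_score_zero(self, rng):
        x = rng.normal(size=500)
        idx = np.arange(200)
        assert compute_miri(x, idx, idx) < 0.03

    def test_disjoint_supports_score_near_one(self, rng):
        x = np.concatenate([rng.uniform(0, 1, 500), rng.uniform(2, 3, 500)])
        lower = np.arange(500)
        upper = np.arange(500, 1000)
        assert compute_miri(x, lower, upper) > 0.95

    def test_shifted_normals_match_analytic_total_variation(self, rng):
        """TV(N(0,1), N(1,1)) = 2 Phi(1/2) - 1 ~ 0.3829."""
        n = 10_000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        lower = np.arange(n)
        upper = np.arange(n, 2 * n)
        expected = 2 * norm.cdf(0.5) - 1
        assert compute_miri(x, lower, upper) == pytest.approx(expected, abs=0.03)

    def test_kde_and_histogram_estimators_agree(self, rng):
        n = 5000
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(0.7, 1.3, n)])
        lower, upper = np.arange(n), np.arange(n, 2 * n)
        kde = compute_miri(x, lower, upper, estimator="kde")
        hist = compute_miri(x, lower, upper, estimator="histogram")
        assert abs(kde - hist) < 0.05

    def test_symmetry_and_index_order_invariance(self, rng):
        x = rng.normal(size=400)
        lower = rng.choice(400, 100, replace=False)
        upper = rng.choice(400, 120, replace=False)
        a = compute_miri(x, lower, upper)
        b = compute_miri(x, upper, lower)
        c = compute_miri(x, rng.permutation(lower), rng.permutation(upper))
        assert a == pytest.approx(b)
        assert a == pytest.approx(c)

    def test_result_stays_in_unit_interval(self, rng):
        for scale in (1e-3, 1.0, 1e3):
            x = rng.normal(0, scale, 300)
            v = compute_miri(x, np.arange(100), np.arange(150, 300))
            assert 0.0 <= v <= 1.0

    def test_small_sets_rejected(self, rng):
        x = rng.normal(size=100)
        with pytest.raises(InsufficientDataError):
            compute_miri(x, np.arange(5), np.arange(50, 100))

    def test_null_correction_zeroes_same_distribution(self, rng):
        """Two samples of one distribution should score ~0 after the
        permutation-null floor is removed."""
        x = rng.normal(size=1000)
        raw = compute_miri(x, np.arange(500), np.arange(500, 1000))
        corrected = compute_miri(x, np.arange(500), np.arange(500, 1000),
                                 null_correction=True, rng=1)
        assert raw > 0.0
        assert corrected < raw
        assert corrected < 0.05


class TestMiriMatrix:
    def test_planted_driver_dominates_and_isolated_parameters_vanish(
        self, toy_chain_model
    ):
        """On the driver->X chain, the X AUC must be most sensitive to the
        planted R->X rate constant, while the isolated receptor's
        parameters are structurally independent of X."""
        m = toy_chain_model
        space = ParameterSpace.from_model(
            m, fixed={"s_R": 0.5, "Ks_R": 0.5, "d_R": 0.1, "d_X": 0.1}
        )
        mean, sd, n_failed = miri_matrix(
            m, space, ["X"], n=800, realizations=3, seed=5
        )
        assert n_failed == 0
        row = mean.loc["X"]
        assert row.idxmax() == "k_R_X"
        for p in ("s_ISO", "Ks_ISO", "d_ISO"):
            assert row[p] <= 3 * max(sd.loc["X", p], 1e-12)
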