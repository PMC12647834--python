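"""Marginal R2 and hierarchical partitioning of predictor-group importance."""

import numpy as np
import pandas as pd
import pytest

from naturadist._glm import cloglog_inverse, fit_cloglog_glm
from naturadist.importance import (
    CLOGLOG_DISTRIBUTION_VARIANCE,
    bootstrap_importance,
    hierarchical_partition,
    marginal_r2,
)

from oracles import shapley_oracle


class _StubFit:
    def __init__(self, params, s2s=0.0, s2r=0.0):
        self.params = np.asarray(params, dtype=float)
        self.sigma2_species = s2s
        self.sigma2_region = s2r


class TestMarginalR2:
    def test_closed_form_unit_fixed_variance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100_000)
        x = (x - x.mean()) / x.std()
        X = np.column_stack([np.ones_like(x), x])
        r2 = marginal_r2(_StubFit([0.3, 1.0]), X, flavor="theoretical")
        assert r2 == pytest.approx(1.0 / (1.0 + np.pi**2 / 6.0), abs=1e-6)
        assert CLOGLOG_DISTRIBUTION_VARIANCE == pytest.approx(1.6449, abs=1e-4)

    def test_null_model_gives_zero(self):
        X = np.column_stack([np.ones(100), np.random.default_rng(1).normal(size=100)])
        assert marginal_r2(_StubFit([0.5, 0.0]), X) == 0.0

    def test_random_effect_variance_shrinks_r2(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([np.ones(1000), rng.normal(size=1000)])
        base = marginal_r2(_StubFit([0.0, 1.0]), X)
        mixed = marginal_r2(_StubFit([0.0, 1.0], s2s=1.0, s2r=1.0), X)
        assert mixed < base

    def test_r2_nondecreasing_with_true_predictor(self):
        rng = np.random.default_rng(3)
        n = 5000
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        y = (rng.random(n) < cloglog_inverse(-1.5 + 0.6 * x1 + 0.6 * x2)).astype(float)
        X1 = np.column_stack([np.ones(n), x1])
        X2 = np.column_stack([np.ones(n), x1, x2])
        r2_small = marginal_r2(fit_cloglog_glm(X1, y), X1)
        r2_big = marginal_r2(fit_cloglog_glm(X2, y), X2)
        assert r2_big >= r2_small

    def test_delta_flavor_differs_but_is_bounded(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = rng.normal(size=n)
        y = (rng.random(n) < cloglog_inverse(-1.0 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(n), x])
        fit = fit_cloglog_glm(X, y)
        for flavor in ("theoretical", "delta"):
            r2 = marginal_r2(fit, X, flavor=flavor)
            assert 0.0 <= r2 <= 1.0


class TestHierarchicalPartition:
    def _sim(self, betas, n=5000, seed=0):
        rng = np.random.default_rng(seed)
        k = len(betas)
        x = rng.normal(size=(n, k))
        eta = -1.8 + x @ np.asarray(betas)
        y = (rng.random(n) < cloglog_inverse(eta)).astype(float)
        X = np.column_stack([np.ones(n), x])
        groups = {f"g{j}": [j + 1] for j in range(k)}
        return X, y, groups

    def test_single_group_gets_everything(self):
        X, y, groups = self._sim([0.7], seed=1)
        part = hierarchical_partition(X, y, {"g0": [1]})
        assert part["share_pct"]["g0"] == pytest.approx(100.0)

    def test_symmetric_groups_split_evenly(self):
        X, y, groups = self._sim([0.5, 0.5], seed=2)
        part = hierarchical_partition(X, y, groups)
        assert part["share_pct"]["g0"] == pytest.approx(50.0, abs=5.0)
        assert part["share_pct"]["g1"] == pytest.approx(50.0, abs=5.0)

    def test_null_group_gets_nothing(self):
        X, y, groups = self._sim([0.7, 0.0], seed=3)
        part = hierarchical_partition(X, y, groups)
        assert part["share_pct"]["g1"] == pytest.approx(0.0, abs=2.0)

    def test_matches_permutation_shapley_oracle(self):
        """3-group partition equals the permutation-averaged marginal gain."""
        X, y, groups = self._sim([0.5, 0.3, -0.4], n=300, seed=4)
        part = hierarchical_partition(X, y, groups)
        names = list(groups)
        from itertools import combinations

        r2 = {}
        for r in range(len(names) + 1):
            for subset in combinations(range(len(names)), r):
                cols = [0] + [groups[names[j]][0] for j in subset]
                fit = fit_cloglog_glm(X[:, cols], y)
                r2[frozenset(subset)] = marginal_r2(fit, X[:, cols])
        oracle = shapley_oracle(r2, names)
        for g in names:
            assert part["contribution"][g] == pytest.approx(oracle[g], abs=1e-8)

    def test_shares_sum_to_100(self):
        X, y, groups = self._sim([0.5, 0.2, -0.3], n=2000, seed=5)
        part = hierarchical_partition(X, y, groups)
        assert sum(part["share_pct"].values()) == pytest.approx(100.0, abs=1e-6)


def _distance_table(n, seed, betas=None):
    rng = np.random.default_rng(seed)
    names = ("pc_temp", "pc_prec", "hmi", "flora_pd", "phylo_dissim", "geo")
    betas = betas or {m: 0.0 for m in names}
    cols = {
        "species_id": [f"s{i % 40}" for i in range(n)],
        "recipient_region_id": [f"r{i % 25}" for i in range(n)],
    }
    eta = np.full(n, -2.0)
    for m in names:
        x = rng.normal(size=n)
        cols[f"d_{m}"] = x
        eta += betas[m] * x
    cols["outcome"] = (rng.random(n) < cloglog_inverse(eta)).astype(int)
    return pd.DataFrame(cols)


class TestBootstrap:
    def test_degenerate_full_sample_equals_direct_partition(self):
        table = _distance_table(800, seed=6, betas={"pc_temp": 0.8, "pc_prec": 0.3,
                                                    "hmi": 0.0, "flora_pd": 0.0,
                                                    "phylo_dissim": 0.0, "geo": 0.0})
        res = bootstrap_importance(table, n_reps=1, sample_size=len(table), seed=0)
        from naturadist.importance import term_groups
        from naturadist.model import build_design

        design = build_design(table, random_effects=False)
        direct = hierarchical_partition(design.X, design.y, term_groups(design))
        got = res.replicates.set_index("group")["share_pct"]
        for g, v in direct["share_pct"].items():
            assert got[g] == pytest.approx(v, abs=1e-9)

    def test_deterministic_under_seed(self):
        table = _distance_table(1500, seed=7, betas={"pc_temp": 0.6, "pc_prec": 0.2,
                                                     "hmi": 0.1, "flora_pd": -0.2,
                                                     "phylo_dissim": 0.0, "geo": 0.0})
        a = bootstrap_importance(table, n_reps=3, sample_size=800, seed=42)
        b = bootstrap_importance(table, n_reps=3, sample_size=800, seed=42)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)

    def test_shares_sum_to_100_per_replicate(self):
        table = _distance_table(1500, seed=8, betas={"pc_temp": 0.6, "pc_prec": 0.2,
                                                     "hmi": 0.1, "flora_pd": -0.2,
                                                     "phylo_dissim": 0.0, "geo": 0.0})
        res = bootstrap_importance(table, n_reps=3, sample_size=800, seed=1)
        sums = res.replicates.groupby("replicate")["share_pct"].sum()
        assert np.abs(sums - 100.0).max() < 1e-6

    def test_sample_size_validated(self):
        table = _distance_table(100, seed=9)
        with pytest.raises(ValueError):
            bootstrap_importance(table, n_reps=1, sample_size=101, seed=0)
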