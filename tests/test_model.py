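"""Design construction, Wald tests, partial effects, peaks and subsets."""

import numpy as np
import pandas as pd
import pytest

from naturadist.model import (
    DesignSpec,
    FittedModel,
    apply_subset,
    build_design,
    partial_effect_curve,
    peak_location,
    standardize_no_center,
    wald_tests,
    Z_95,
)


class TestStandardize:
    def test_two_values(self):
        scaled, factor = standardize_no_center([2.0, 4.0])
        assert factor == pytest.approx(np.sqrt(2.0))
        assert scaled == pytest.approx([1.41421356, 2.82842712])

    def test_unit_sd_idempotent(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        x = x / x.std(ddof=1)
        scaled, factor = standardize_no_center(x)
        assert factor == pytest.approx(1.0, abs=1e-12)
        assert np.abs(scaled - x).max() < 1e-12

    def test_exact_inverse(self):
        x = np.array([3.0, -1.0, 7.0, 2.0])
        scaled, factor = standardize_no_center(x)
        assert scaled * factor == pytest.approx(x, rel=1e-15)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            standardize_no_center([1.0, 1.0, 1.0])


def test_build_design_quadratic_is_square_of_scaled_linear():
    rng = np.random.default_rng(1)
    n = 200
    table = pd.DataFrame(
        {
            "species_id": [f"s{i%20}" for i in range(n)],
            "recipient_region_id": [f"r{i%10}" for i in range(n)],
            "outcome": rng.integers(0, 2, n),
            **{f"d_{m}": rng.normal(size=n) for m in ("pc_temp", "pc_prec", "hmi", "flora_pd", "phylo_dissim", "geo")},
        }
    )
    design = build_design(table)
    j = design.terms.index("pc_temp_linear")
    assert np.allclose(design.X[:, j + 1], design.X[:, j] ** 2)
    assert np.ptp(design.X[:, 0]) == 0.0  # intercept


def _manual_model(coefs, ses=None, scaling=None, means=None):
    predictors = tuple(sorted({t.rsplit("_", 1)[0] for t in coefs if t != "(Intercept)"}))
    scaling = scaling or {p: 1.0 for p in predictors}
    rows = []
    for t, b in coefs.items():
        kind = (
            "intercept" if t == "(Intercept)"
            else "linear" if t.endswith("_linear")
            else "quadratic"
        )
        pred = None if kind == "intercept" else t.rsplit("_", 1)[0]
        rows.append({"term": t, "predictor": pred, "kind": kind, "estimate": b,
                     "se": (ses or {}).get(t, 1.0)})
    spec = DesignSpec(
        predictors=predictors,
        scaling=scaling,
        column_means=means or {t: 0.0 for t in coefs},
        random_effects=False,
    )
    return FittedModel(
        coefficients=pd.DataFrame(rows), sigma2_species=0.0, sigma2_region=0.0,
        link="cloglog", loglik=0.0, converged=True, n_obs=0, spec=spec,
    )


class TestWald:
    def test_null_estimate(self):
        m = _manual_model({"(Intercept)": 0.0})
        t = wald_tests(m).iloc[0]
        assert t["z"] == 0.0
        assert t["p"] == pytest.approx(1.0)
        assert (t["ci_low"], t["ci_high"]) == pytest.approx((-Z_95, Z_95))

    def test_z_of_1_96_gives_p_05(self):
        m = _manual_model({"(Intercept)": 1.959964})
        assert wald_tests(m).iloc[0]["p"] == pytest.approx(0.05, abs=1e-6)

    def test_ci_width_scales_with_se(self):
        m = _manual_model({"(Intercept)": 1.0}, ses={"(Intercept)": 3.0})
        t = wald_tests(m).iloc[0]
        assert t["ci_high"] - t["ci_low"] == pytest.approx(2 * Z_95 * 3.0)


class TestPartialEffects:
    def test_all_beta_zero_gives_flat_intercept_curve(self):
        coefs = {"(Intercept)": -2.0}
        for p in ("pc_temp", "geo"):
            coefs[f"{p}_linear"] = 0.0
            coefs[f"{p}_quadratic"] = 0.0
        m = _manual_model(coefs)
        curve = partial_effect_curve(m, "pc_temp", grid=np.linspace(-2, 2, 21))
        expected = 1 - np.exp(-np.exp(-2.0))
        assert np.abs(curve["probability"] - expected).max() < 1e-12

    def test_pure_quadratic_peaks_at_zero(self):
        coefs = {
            "(Intercept)": -2.0,
            "pc_temp_linear": 0.0,
            "pc_temp_quadratic": -1.0,
        }
        m = _manual_model(coefs)
        curve = partial_effect_curve(m, "pc_temp", grid=np.linspace(-3, 3, 61))
        assert curve.loc[curve["probability"].idxmax(), "grid_std"] == pytest.approx(0.0)

    def test_curve_max_matches_peak_location(self):
        coefs = {
            "(Intercept)": -2.5,
            "geo_linear": 0.95,
            "geo_quadratic": -0.12,
        }
        m = _manual_model(coefs, scaling={"geo": 2.0})
        grid = np.linspace(0, 8, 161)
        curve = partial_effect_curve(m, "geo", grid=grid)
        argmax = curve.loc[curve["probability"].idxmax(), "grid_std"]
        pk = peak_location(0.95, -0.12, scaling_factor=2.0)
        assert abs(argmax - pk.x_star_std) <= grid[1] - grid[0]
        assert pk.x_star_raw == pytest.approx(pk.x_star_std * 2.0)

    def test_unknown_predictor_rejected(self):
        m = _manual_model({"(Intercept)": 0.0, "geo_linear": 1.0, "geo_quadratic": 0.0})
        with pytest.raises(ValueError):
            partial_effect_curve(m, "nope")


class TestPeakLocation:
    def test_symmetric_parabola(self):
        pk = peak_location(0.0, -1.0)
        assert pk.valid and pk.x_star_std == 0.0

    def test_printed_coefficient_pair(self):
        # beta1=0.95, beta2=-0.12: peak at -0.95/(2 * -0.12)
        pk = peak_location(0.95, -0.12)
        assert pk.x_star_std == pytest.approx(3.9583, abs=1e-4)

    def test_positive_quadratic_invalid(self):
        assert not peak_location(1.0, 0.5).valid

    def test_zero_quadratic_never_divides(self):
        pk = peak_location(1.0, 0.0)
        assert not pk.valid and np.isnan(pk.x_star_std)

    def test_significance_gate(self):
        assert not peak_location(1.0, -0.5, p_quadratic=0.2).valid
        assert peak_location(1.0, -0.5, p_quadratic=0.001).valid


class TestSubsets:
    def _table(self, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(5):
            n_succ = 3
            n_fail = [500, 20, 100, 50, 7][s]
            for i in range(n_succ + n_fail):
                rows.append(
                    {
                        "species_id": f"s{s}",
                        "recipient_region_id": f"r{i}",
                        "outcome": 1 if i < n_succ else 0,
                        "d_geo": rng.normal(),
                    }
                )
        return pd.DataFrame(rows)

    def test_min_naturalized_k1_is_identity(self):
        t = self._table()
        out = apply_subset(t, "min_naturalized_regions", k=1)
        assert len(out) == len(t)

    def test_failure_subsample_counts_and_cap(self):
        t = self._table()
        out = apply_subset(t, "failure_subsample", m=10, seed=1)
        per = out.groupby("species_id").apply(
            lambda g: (int(g["outcome"].sum()), int((1 - g["outcome"]).sum())),
            include_groups=False,
        )
        assert per["s0"] == (3, 30)  # 10x successes available
        assert per["s1"] == (3, 20)  # capped at available failures
        assert per["s4"] == (3, 7)

    def test_failure_subsample_deterministic(self):
        t = self._table()
        a = apply_subset(t, "failure_subsample", m=10, seed=5)
        b = apply_subset(t, "failure_subsample", m=10, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_island_mainland_partition(self):
        t = self._table()
        is_island = {r: (hash(r) % 2 == 0) for r in t["recipient_region_id"]}
        a = apply_subset(t, "island_only", region_is_island=is_island)
        b = apply_subset(t, "mainland_only", region_is_island=is_island)
        assert len(a) + len(b) == len(t)

    def test_continent_restriction(self):
        t = pd.DataFrame(
            {
                "species_id": ["s0"] * 4,
                "recipient_region_id": ["r0", "r1", "r2", "r3"],
                "outcome": [1, 0, 0, 0],
                "d_geo": [0.1, 0.2, 0.3, 0.4],
            }
        )
        cont = {"r0": "cA", "r1": "cA", "r2": "cB", "r3": "cB"}
        out = apply_subset(t, "continent", region_continent=cont)
        assert set(out["recipient_region_id"]) == {"r0", "r1"}

    def test_species_flag_subset(self):
        t = self._table()
        out = apply_subset(t, "species_flag", species=["s1", "s3"])
        assert set(out["species_id"]) == {"s1", "s3"}

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            apply_subset(self._table(), "bogus")
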