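"""Naturalization model: design construction, fitting and post-estimation.

Predictors are the six donor-recipient distances, each entering with a linear
and a quadratic term. Standardization divides by the sample SD *without
centring* (so a zero distance stays zero, and the quadratic term is exactly
the square of the scaled linear term, preserving the peak geometry
x* = -beta1 / (2 beta2) on the standardized scale). The model is binomial
with a complementary log-log link; species and region enter as crossed random
intercepts unless disabled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_cloglog_glm, cloglog_inverse
from ._glmm import fit_cloglog_glmm

__all__ = [
    "DEFAULT_PREDICTORS",
    "Z_95",
    "DesignSpec",
    "Design",
    "FittedModel",
    "PeakResult",
    "standardize_no_center",
    "build_design",
    "fit_model",
    "wald_tests",
    "partial_effect_curve",
    "peak_location",
    "apply_subset",
]

DEFAULT_PREDICTORS = ("pc_temp", "pc_prec", "hmi", "flora_pd", "phylo_dissim", "geo")

#: normal 97.5% quantile used for all Wald confidence intervals
Z_95 = 1.959964


def standardize_no_center(values):
    """Divide by the sample SD (n-1 denominator) without removing the mean.

    Returns ``(scaled, factor)``; multiplying back by ``factor`` recovers the
    input exactly. A zero SD raises (degenerate predictor).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standardize_no_center needs at least 2 values")
    factor = float(x.std(ddof=1))
    if factor == 0.0:
        raise ValueError("degenerate predictor: zero sample SD")
    return x / factor, factor


@dataclass
class DesignSpec:
    predictors: tuple
    scaling: dict  # predictor -> sample SD divisor
    column_means: dict  # term -> mean of the (scaled) design column
    random_effects: bool


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    terms: list  # "(Intercept)", "<name>_linear", "<name>_quadratic", ...
    spec: DesignSpec
    species: np.ndarray | None
    region: np.ndarray | None


def build_design(
    distance_table: pd.DataFrame,
    predictors=DEFAULT_PREDICTORS,
    random_effects: bool = True,
) -> Design:
    """Build the fixed-effect design matrix from a distance table.

    Columns: intercept, then per predictor the scaled linear term and its
    square.
    """
    predictors = tuple(predictors)
    n = len(distance_table)
    cols = [np.ones(n)]
    terms = ["(Intercept)"]
    scaling: dict = {}
    for name in predictors:
        xs, factor = standardize_no_center(distance_table[f"d_{name}"].to_numpy())
        scaling[name] = factor
        cols.append(xs)
        cols.append(xs**2)
        terms += [f"{name}_linear", f"{name}_quadratic"]
    X = np.column_stack(cols)
    spec = DesignSpec(
        predictors=predictors,
        scaling=scaling,
        column_means={t: float(X[:, j].mean()) for j, t in enumerate(terms)},
        random_effects=random_effects,
    )
    return Design(
        X=X,
        y=distance_table["outcome"].to_numpy(dtype=float),
        terms=terms,
        spec=spec,
        species=distance_table["species_id"].to_numpy() if random_effects else None,
        region=distance_table["recipient_region_id"].to_numpy() if random_effects else None,
    )


@dataclass
class FittedModel:
    """Coefficients, variance components and metadata of one fitted model."""

    coefficients: pd.DataFrame  # term, predictor, kind, estimate, se
    sigma2_species: float
    sigma2_region: float
    link: str
    loglik: float
    converged: bool
    n_obs: int
    spec: DesignSpec
    fit: object = field(repr=False, default=None)

    def coef(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.set_index("term").loc[term, "se"])


def _tidy(terms, params, ses) -> pd.DataFrame:
    rows = []
    for t, b, s in zip(terms, params, ses):
        if t == "(Intercept)":
            pred, kind = None, "intercept"
        elif t.endswith("_linear"):
            pred, kind = t[: -len("_linear")], "linear"
        else:
            pred, kind = t[: -len("_quadratic")], "quadratic"
        rows.append({"term": t, "predictor": pred, "kind": kind, "estimate": b, "se": s})
    return pd.DataFrame(rows)


def fit_model(design: Design, laplace_refine: bool = True, **kwargs) -> FittedModel:
    """Fit the cloglog model for a design (GLMM if it has random effects)."""
    if design.spec.random_effects:
        fit = fit_cloglog_glmm(
            design.X,
            design.y,
            species=design.species,
            region=design.region,
            columns=design.terms,
            laplace_refine=laplace_refine,
            **kwargs,
        )
        s2s, s2r = fit.sigma2_species, fit.sigma2_region
        ll = fit.loglik_laplace
    else:
        fit = fit_cloglog_glm(design.X, design.y, columns=design.terms, **kwargs)
        s2s = s2r = 0.0
        ll = fit.loglik
    return FittedModel(
        coefficients=_tidy(design.terms, fit.params, fit.se),
        sigma2_species=s2s,
        sigma2_region=s2r,
        link="cloglog",
        loglik=float(ll),
        converged=fit.converged,
        n_obs=len(design.y),
        spec=design.spec,
        fit=fit,
    )


def wald_tests(model: FittedModel) -> pd.DataFrame:
    """Two-sided Wald z-tests and 95% CIs, no multiplicity adjustment."""
    out = model.coefficients.copy()
    z = out["estimate"] / out["se"]
    out["z"] = z
    out["p"] = 2.0 * stats.norm.sf(np.abs(z))
    out["ci_low"] = out["estimate"] - Z_95 * out["se"]
    out["ci_high"] = out["estimate"] + Z_95 * out["se"]
    return out


def partial_effect_curve(
    model: FittedModel,
    predictor: str,
    grid: np.ndarray | None = None,
    n_points: int = 101,
    grid_range: tuple | None = None,
) -> pd.DataFrame:
    """Predicted naturalization probability along one standardized distance.

    Other predictors are held at the mean of their scaled linear column (the
    quadratic contribution uses that mean squared); random effects are set to
    zero. Returns the grid on the standardized and the raw scale together
    with the predicted probability.
    """
    if predictor not in model.spec.predictors:
        raise ValueError(f"unknown predictor {predictor!r}")
    means = model.spec.column_means
    base = model.coef("(Intercept)")
    for other in model.spec.predictors:
        if other == predictor:
            continue
        m = means[f"{other}_linear"]
        base += model.coef(f"{other}_linear") * m + model.coef(f"{other}_quadratic") * m**2
    if grid is None:
        if grid_range is None:
            center = means[f"{predictor}_linear"]
            grid_range = (center - 3.0, center + 3.0)
        grid = np.linspace(grid_range[0], grid_range[1], n_points)
    grid = np.asarray(grid, dtype=float)
    b1 = model.coef(f"{predictor}_linear")
    b2 = model.coef(f"{predictor}_quadratic")
    eta = base + b1 * grid + b2 * grid**2
    return pd.DataFrame(
        {
            "predictor": predictor,
            "grid_std": grid,
            "grid_raw": grid * model.spec.scaling[predictor],
            "probability": cloglog_inverse(eta),
        }
    )


@dataclass
class PeakResult:
    """Interior optimum of a quadratic distance-probability relationship."""

    predictor: str | None
    x_star_std: float  # -beta1 / (2 beta2), standardized units
    x_star_raw: float  # x_star_std * scaling factor
    valid: bool


def peak_location(
    beta1: float,
    beta2: float,
    scaling_factor: float = 1.0,
    p_quadratic: float | None = None,
    alpha_level: float = 0.05,
    predictor: str | None = None,
) -> PeakResult:
    """Peak of the quadratic linear predictor, when one exists.

    Valid only for beta2 < 0 (and, when ``p_quadratic`` is supplied,
    significant at ``alpha_level``); beta2 >= 0 yields an invalid flag,
    never a division error.
    """
    valid = np.isfinite(beta1) and np.isfinite(beta2) and beta2 < 0.0
    if valid and p_quadratic is not None:
        valid = p_quadratic < alpha_level
    if not valid:
        return PeakResult(predictor, np.nan, np.nan, False)
    x_star = -beta1 / (2.0 * beta2)
    return PeakResult(predictor, float(x_star), float(x_star * scaling_factor), True)


# ---------------------------------------------------------------------------
# sensitivity subsets
# ---------------------------------------------------------------------------

def apply_subset(distance_table: pd.DataFrame, rule: str, **params) -> pd.DataFrame:
    """Sensitivity-analysis subsets of the modelling table.

    Rules
    -----
    - ``continent``: keep candidate recipients on continents where the species
      has naturalized at least once (requires ``region_continent`` mapping).
    - ``species_flag``: keep a supplied species list (``species``).
    - ``min_naturalized_regions``: keep species naturalized in >= ``k`` regions.
    - ``failure_subsample``: per species keep all successes plus ``m`` times as
      many randomly chosen failures (capped at availability; needs ``seed``).
    - ``island_only`` / ``mainland_only``: restrict recipient regions by the
      ``region_is_island`` mapping.
    """
    t = distance_table
    if rule == "continent":
        cont = params["region_continent"]
        rc = t["recipient_region_id"].map(cont)
        hits = t[t["outcome"] == 1]
        nat_cont = hits.groupby("species_id")["recipient_region_id"].apply(
            lambda s: {cont[r] for r in s}
        )
        allowed = [
            c in nat_cont.get(sp, set())
            for sp, c in zip(t["species_id"], rc)
        ]
        return t[np.asarray(allowed)].reset_index(drop=True)
    if rule == "species_flag":
        keep = set(params["species"])
        return t[t["species_id"].isin(keep)].reset_index(drop=True)
    if rule == "min_naturalized_regions":
        k = int(params["k"])
        counts = t.groupby("species_id")["outcome"].sum()
        keep = set(counts[counts >= k].index)
        return t[t["species_id"].isin(keep)].reset_index(drop=True)
    if rule == "failure_subsample":
        m = int(params["m"])
        rng = np.random.default_rng(params["seed"])
        pieces = []
        for sp, grp in t.groupby("species_id", sort=True):
            succ = grp[grp["outcome"] == 1]
            fail = grp[grp["outcome"] == 0]
            n_keep = min(m * len(succ), len(fail))
            pieces.append(succ)
            if n_keep:
                pieces.append(fail.sample(n=n_keep, random_state=rng.integers(2**31)))
        return pd.concat(pieces).sort_index().reset_index(drop=True)
    if rule in ("island_only", "mainland_only"):
        island = t["recipient_region_id"].map(params["region_is_island"]).astype(bool)
        keep = island if rule == "island_only" else ~island
        return t[keep].reset_index(drop=True)
    raise ValueError(f"unknown subset rule {rule!r}")
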