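"""Reduce 19 bioclimatic variables to two climate axes (PC_Temp, PC_Prec).

Skewed variables are first passed through a monotone normalizing transform
chosen to minimize |sample skewness| among four candidates (identity,
shifted log, shifted square root, Box-Cox), then all variables are scaled to
mean 0 / SD 1 and a PCA is fitted on cells. The first axis is oriented so it
correlates positively with annual mean temperature (bioclim_1) and the second
with annual precipitation (bioclim_12): higher PC_Temp means warmer and less
seasonal, higher PC_Prec wetter and less seasonal. Region-level climate is
the unweighted mean of cell scores (every overlapping cell counts once).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

__all__ = [
    "TransformSpec",
    "PcaModel",
    "select_transform",
    "fit_pca",
    "transform_scores",
    "region_pc_means",
]

BIOCLIM_COLUMNS = [f"bioclim_{i}" for i in range(1, 20)]


@dataclass
class TransformSpec:
    """A fitted monotone normality transform for one variable."""

    transform_id: str  # identity | log-shift | sqrt-shift | box-cox
    shift: float = 0.0
    lmbda: float | None = None  # Box-Cox exponent
    zero_variance: bool = False

    def apply(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.transform_id == "identity":
            return x
        if self.transform_id == "log-shift":
            return np.log(x + self.shift)
        if self.transform_id == "sqrt-shift":
            return np.sqrt(x + self.shift)
        if self.transform_id == "box-cox":
            return stats.boxcox(x + self.shift, lmbda=self.lmbda)
        raise ValueError(f"unknown transform {self.transform_id!r}")


_TIE_ORDER = ("identity", "log-shift", "sqrt-shift", "box-cox")


def select_transform(values) -> TransformSpec:
    """Pick the candidate transform minimizing |sample skewness|.

    A later (more complex) candidate only wins if it reduces |skewness| by
    more than sqrt(6/n) — roughly the sampling SD of skewness under
    normality — so near-ties break in favour of identity, then log-shift,
    sqrt-shift, Box-Cox. Requires >= 10 finite values; a constant vector
    returns identity flagged as zero-variance.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("select_transform requires at least 10 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("select_transform requires finite values")
    if np.ptp(x) == 0.0:
        return TransformSpec("identity", zero_variance=True)

    # shift so the support is strictly positive for log/sqrt/box-cox
    shift = float(max(0.0, -x.min()) + 1e-3 * np.ptp(x))

    candidates: list[TransformSpec] = [TransformSpec("identity")]
    candidates.append(TransformSpec("log-shift", shift=shift))
    candidates.append(TransformSpec("sqrt-shift", shift=shift))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lam = stats.boxcox(x + shift)
        candidates.append(TransformSpec("box-cox", shift=shift, lmbda=float(lam)))
    except Exception:  # degenerate Box-Cox fit: skip the candidate
        pass

    margin = float(np.sqrt(6.0 / x.size))
    best = None
    best_skew = np.inf
    for spec in candidates:
        s = abs(float(stats.skew(spec.apply(x))))
        if s < best_skew - margin:
            best, best_skew = spec, s
    assert best is not None
    return best


@dataclass
class PcaModel:
    """Fitted 2-axis climate PCA (loadings, scalings, orientation)."""

    variables: list
    loadings: np.ndarray  # (n_vars, 2), orientation applied
    explained_variance_fraction: np.ndarray  # all retained axes of the full PCA
    means: np.ndarray
    sds: np.ndarray
    orientation: tuple
    transforms: dict = field(default_factory=dict)  # variable -> TransformSpec
    dropped: list = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "variables": list(self.variables),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "orientation": list(self.orientation),
            "transforms": {k: asdict(v) for k, v in self.transforms.items()},
            "dropped": list(self.dropped),
        }
        return json.dumps(payload, indent=2)


def fit_pca(cell_table: pd.DataFrame, transform_specs: dict | None = None, columns=None) -> PcaModel:
    """Fit the climate PCA on transformed, scaled cell values.

    ``transform_specs`` maps variable name to a :class:`TransformSpec`; when
    omitted, :func:`select_transform` is run per variable. Variables that are
    constant after transform are dropped with a warning. Axis signs are chosen
    so PC_Temp correlates positively with ``bioclim_1`` and PC_Prec with
    ``bioclim_12``.
    """
    columns = list(columns or [c for c in BIOCLIM_COLUMNS if c in cell_table.columns])
    if len(cell_table) < len(columns):
        raise ValueError("need at least as many cells as variables")
    if transform_specs is None:
        transform_specs = {c: select_transform(cell_table[c].to_numpy()) for c in columns}

    kept, dropped, mats = [], [], []
    for c in columns:
        z = transform_specs[c].apply(cell_table[c].to_numpy())
        if np.ptp(z) == 0.0 or transform_specs[c].zero_variance:
            dropped.append(c)
            continue
        kept.append(c)
        mats.append(z)
    if len(kept) < 2:
        raise ValueError("degenerate input: fewer than 2 non-constant variables")
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}")

    mat = np.column_stack(mats)
    means = mat.mean(axis=0)
    sds = mat.std(axis=0, ddof=1)
    scaled = (mat - means) / sds

    pca = PCA(n_components=min(len(kept), scaled.shape[0]))
    scores = pca.fit_transform(scaled)
    loadings = pca.components_[:2].T.copy()  # (n_vars, 2)

    signs = []
    for axis, anchor in enumerate(("bioclim_1", "bioclim_12")):
        if anchor in kept:
            r = np.corrcoef(scores[:, axis], cell_table[anchor].to_numpy())[0, 1]
        else:
            r = loadings[0, axis]
        signs.append(-1.0 if r < 0 else 1.0)
    loadings *= np.asarray(signs)

    return PcaModel(
        variables=kept,
        loadings=loadings,
        explained_variance_fraction=pca.explained_variance_ratio_.copy(),
        means=means,
        sds=sds,
        orientation=tuple(signs),
        transforms={c: transform_specs[c] for c in columns},
        dropped=dropped,
    )


def transform_scores(model: PcaModel, cell_table: pd.DataFrame) -> pd.DataFrame:
    """Project cells onto the oriented PC_Temp / PC_Prec axes."""
    mat = np.column_stack(
        [model.transforms[c].apply(cell_table[c].to_numpy()) for c in model.variables]
    )
    scaled = (mat - model.means) / model.sds
    scores = scaled @ model.loadings
    return pd.DataFrame(
        {
            "cell_id": cell_table["cell_id"].to_numpy(),
            "region_id": cell_table["region_id"].to_numpy(),
            "pc_temp": scores[:, 0],
            "pc_prec": scores[:, 1],
        }
    )


def region_pc_means(cell_scores: pd.DataFrame, regions=None) -> pd.DataFrame:
    """Unweighted per-region means of cell PC scores.

    Every cell counts once in full (no partial-overlap weighting). If
    ``regions`` (an iterable of region ids) is given, a region without any
    cell raises a missing-data error naming it.
    """
    out = (
        cell_scores.groupby("region_id", sort=True)[["pc_temp", "pc_prec"]]
        .mean()
        .reset_index()
    )
    if regions is not None:
        missing = sorted(set(regions) - set(out["region_id"]))
        if missing:
            raise ValueError(f"regions without any grid cell: {missing}")
        out = out.set_index("region_id").loc[list(regions)].reset_index()
    return out
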