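"""Assemble the species x candidate-recipient table of the six distances.

For every species, candidate recipient regions are all regions outside its
native range. Bidirectional distances (PC_Temp, PC_Prec, HMI, area-corrected
flora PD) are signed, recipient minus donor; unidirectional distances
(phylogenetic Simpson dissimilarity, centroid great-circle distance) are
non-negative area-weighted means over donor regions, weighting each donor by
its area. The flora-diversity distance compares the recipient's area-corrected
residual with the *donor-union* residual (one subtraction); a per-donor
area-weighted variant is available as a switch.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .phylo import TreeIndex

__all__ = [
    "bidirectional_distance",
    "unidirectional_weighted_mean",
    "great_circle_km",
    "pairwise_dissimilarity_matrix",
    "build_distance_table",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

DISTANCE_COLUMNS = [
    "d_pc_temp",
    "d_pc_prec",
    "d_hmi",
    "d_flora_pd",
    "d_phylo_dissim",
    "d_geo",
]


def _weights(donor_areas) -> np.ndarray:
    w = np.asarray(donor_areas, dtype=float)
    if w.size == 0:
        raise ValueError("at least one donor region is required")
    if np.any(w <= 0):
        raise ValueError("donor areas must be positive")
    return w


def bidirectional_distance(recipient_value: float, donor_values, donor_areas) -> float:
    """Signed distance: recipient value minus the area-weighted donor mean.

    Equivalently the area-weighted mean of pairwise (recipient - donor)
    differences.
    """
    v = np.asarray(donor_values, dtype=float)
    w = _weights(donor_areas)
    if v.shape != w.shape:
        raise ValueError("donor_values and donor_areas must have the same length")
    if not (np.isfinite(recipient_value) and np.all(np.isfinite(v))):
        raise ValueError("values must be finite")
    return float(recipient_value - np.average(v, weights=w))


def unidirectional_weighted_mean(pair_values, donor_areas) -> float:
    """Area-weighted mean of non-negative per-donor pairwise values."""
    v = np.asarray(pair_values, dtype=float)
    w = _weights(donor_areas)
    if v.shape != w.shape:
        raise ValueError("pair_values and donor_areas must have the same length")
    if np.any(v < 0):
        raise ValueError("pair values must be non-negative")
    return float(np.average(v, weights=w))


def great_circle_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Haversine great-circle distance (spherical Earth, R = 6371 km)."""
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ValueError(f"latitude out of range: {lat}")
    for lon in (lon1, lon2):
        if not -360.0 <= lon <= 360.0:
            raise ValueError(f"longitude out of range: {lon}")
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dp = p2 - p1
    dl = np.deg2rad(lon2 - lon1)
    h = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def _haversine_matrix(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    p = np.deg2rad(lat)[:, None]
    l = np.deg2rad(lon)[:, None]
    h = np.sin((p - p.T) / 2.0) ** 2 + np.cos(p) * np.cos(p.T) * np.sin((l - l.T) / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_dissimilarity_matrix(
    index: TreeIndex, masks: list, flavor: str = "phylogenetic"
) -> np.ndarray:
    """Symmetric Simpson dissimilarity matrix over a list of tip masks.

    Vectorized over the tree's edge table: the shared branch length of a pair
    is a dot product of edge-membership indicators. Empty communities yield
    NaN rows/columns.
    """
    n = len(masks)
    mask_mat = np.vstack([m.astype(bool) for m in masks])
    nonempty = mask_mat.any(axis=1)
    if flavor == "phylogenetic":
        edge_ind = np.vstack([index.edge_mask(m) for m in mask_mat]).astype(float)
        a = (edge_ind * index.edge_lengths) @ edge_ind.T
        pd_tot = np.diag(a).copy()
    elif flavor == "taxonomic":
        memb = mask_mat.astype(float)
        a = memb @ memb.T
        pd_tot = np.diag(a).copy()
    else:
        raise ValueError(f"unknown dissimilarity flavor {flavor!r}")
    b = pd_tot[:, None] - a
    c = pd_tot[None, :] - a
    m = np.minimum(b, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(a + m > 0, m / (a + m), 0.0)
    out[~nonempty, :] = np.nan
    out[:, ~nonempty] = np.nan
    np.fill_diagonal(out, np.where(nonempty, 0.0, np.nan))
    return out


def build_distance_table(
    regions: pd.DataFrame,
    flora: pd.DataFrame,
    region_climate: pd.DataFrame,
    region_hmi: Mapping,
    region_flora_resid: Mapping,
    union_flora_resid: Mapping,
    tree_index: TreeIndex,
    outcomes: pd.DataFrame | None = None,
    dissim_flavor: str = "phylogenetic",
    flora_distance_mode: str = "union",
) -> pd.DataFrame:
    """One row per (species, candidate recipient region) with all six distances.

    ``outcomes`` (species_id, recipient_region_id, outcome) marks naturalization
    successes; absent pairs count as failures. Species without any native
    region in ``flora`` are skipped with a logged count. Rows with undefined
    distances (e.g. a recipient region with an empty native flora) are dropped
    with a logged count.

    ``flora_distance_mode``: "union" (default) subtracts the donor-union
    residual; "per_donor" takes the area-weighted mean of per-donor residual
    differences.
    """
    if flora_distance_mode not in ("union", "per_donor"):
        raise ValueError(f"unknown flora_distance_mode {flora_distance_mode!r}")
    region_ids = list(regions["region_id"])
    r_pos = {r: i for i, r in enumerate(region_ids)}
    nr = len(region_ids)

    areas = regions["area_km2"].to_numpy(dtype=float)
    clim = region_climate.set_index("region_id").loc[region_ids]
    pc_temp = clim["pc_temp"].to_numpy(dtype=float)
    pc_prec = clim["pc_prec"].to_numpy(dtype=float)
    hmi = np.array([region_hmi[r] for r in region_ids], dtype=float)
    resid = np.array([region_flora_resid.get(r, np.nan) for r in region_ids], dtype=float)

    native = flora[flora["status"] == "native"]
    donor_map = native.groupby("species_id")["region_id"].apply(
        lambda s: sorted(set(s))
    )

    region_masks = []
    native_by_region = {
        rid: grp["species_id"] for rid, grp in native.groupby("region_id")
    }
    for rid in region_ids:
        sp = native_by_region.get(rid)
        mask = tree_index.tip_mask(sp) if sp is not None else np.zeros(tree_index.n_tips, bool)
        region_masks.append(mask)
    dissim = pairwise_dissimilarity_matrix(tree_index, region_masks, flavor=dissim_flavor)
    geo = _haversine_matrix(
        regions["centroid_lat"].to_numpy(float), regions["centroid_lon"].to_numpy(float)
    )

    success: set = set()
    if outcomes is not None:
        hits = outcomes[outcomes["outcome"] == 1]
        success = set(zip(hits["species_id"], hits["recipient_region_id"]))

    all_species = sorted(set(flora["species_id"]))
    skipped_no_native = 0
    dropped_nan = 0
    chunks = []
    for sp in all_species:
        if sp not in donor_map.index:
            skipped_no_native += 1
            continue
        donors = np.array([r_pos[r] for r in donor_map[sp]], dtype=int)
        cand = np.setdiff1d(np.arange(nr), donors)
        if cand.size == 0:
            continue
        w = areas[donors]
        wsum = w.sum()
        d_pc_temp = pc_temp[cand] - np.dot(pc_temp[donors], w) / wsum
        d_pc_prec = pc_prec[cand] - np.dot(pc_prec[donors], w) / wsum
        d_hmi = hmi[cand] - np.dot(hmi[donors], w) / wsum
        if flora_distance_mode == "union":
            d_flora = resid[cand] - union_flora_resid[sp]
        else:
            d_flora = ((resid[cand][:, None] - resid[donors][None, :]) @ w) / wsum
        d_dis = dissim[np.ix_(cand, donors)] @ w / wsum
        d_geo = geo[np.ix_(cand, donors)] @ w / wsum

        cand_ids = [region_ids[i] for i in cand]
        out = np.array([(sp, rid) in success for rid in cand_ids], dtype=int)
        chunks.append(
            pd.DataFrame(
                {
                    "species_id": sp,
                    "recipient_region_id": cand_ids,
                    "d_pc_temp": d_pc_temp,
                    "d_pc_prec": d_pc_prec,
                    "d_hmi": d_hmi,
                    "d_flora_pd": d_flora,
                    "d_phylo_dissim": d_dis,
                    "d_geo": d_geo,
                    "outcome": out,
                }
            )
        )
    if not chunks:
        raise ValueError("no species with known native regions")
    table = pd.concat(chunks, ignore_index=True)
    bad = ~np.isfinite(table[DISTANCE_COLUMNS].to_numpy(float)).all(axis=1)
    dropped_nan = int(bad.sum())
    if skipped_no_native:
        logger.info("skipped %d species without native-range data", skipped_no_native)
    if dropped_nan:
        logger.info("dropped %d rows with undefined distances", dropped_nan)
        table = table[~bad].reset_index(drop=True)
    return table
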