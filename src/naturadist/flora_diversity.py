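"""Per-region and per-species-donor-union diversity with area correction.

Taxonomic diversity is native species richness; phylogenetic diversity is
Faith's PD (root path included). Because both scale with area (species-area
relationship), the analysis uses *area-corrected* diversity: the residual of
an OLS regression of log(diversity) on log(area), fitted by default on the
pooled set of region records and species donor-union records.

Species missing from the tree are grafted as new ultrametric-preserving tips
at the root of their genus (MRCA of congeners; the congener's parent node for
a monotypic genus), falling back to the family root when no congener exists.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import dendropy

from .phylo import TreeIndex, faith_pd, node_depth

__all__ = [
    "UnresolvableTaxonError",
    "AreaCorrectionFit",
    "graft_missing",
    "region_diversity",
    "donor_union_metrics",
    "area_correction",
]


class UnresolvableTaxonError(ValueError):
    """Missing species with neither a genus nor a family anchor in the tree."""


def graft_missing(tree: dendropy.Tree, missing_species, genus_map: dict, family_map: dict) -> dendropy.Tree:
    """Attach missing species to a copy of ``tree``, preserving ultrametricity.

    Each missing species becomes a pendant tip at the root node of its genus
    clade (the MRCA of its congeners, or — for a monotypic genus — the parent
    node of the single congener tip), with branch length equal to that node's
    distance to its tips. When the genus has no tip at all, the species is
    grafted at the root of its family instead. Species resolvable to neither
    raise :class:`UnresolvableTaxonError` listing them.
    """
    missing_species = list(missing_species)
    tree = tree.clone(depth=1)
    tree.taxon_namespace = dendropy.TaxonNamespace(
        [t.label for t in tree.taxon_namespace]
    )
    tree.migrate_taxon_namespace(tree.taxon_namespace)

    tree.is_rooted = True
    original_leaves = list(tree.leaf_node_iter())

    def tips_of(group_map: dict, group: str):
        members = {sp for sp, g in group_map.items() if g == group}
        return [lf for lf in original_leaves if lf.taxon.label in members]

    # resolve every anchor against the original topology first: grafted tips
    # never serve as anchors and grafting order cannot matter
    anchors = {}
    unresolved = []
    for sp in missing_species:
        anchor = None
        genus = genus_map.get(sp)
        if genus is not None:
            congeners = tips_of(genus_map, genus)
            if len(congeners) == 1:
                anchor = congeners[0].parent_node
            elif len(congeners) > 1:
                anchor = tree.mrca(taxa=[lf.taxon for lf in congeners])
        if anchor is None:
            fam = family_map.get(sp)
            if fam is not None:
                relatives = tips_of(family_map, fam)
                if len(relatives) == 1:
                    anchor = relatives[0].parent_node
                elif len(relatives) > 1:
                    anchor = tree.mrca(taxa=[lf.taxon for lf in relatives])
        if anchor is None:
            unresolved.append(sp)
        else:
            anchors[sp] = (anchor, node_depth(anchor))
    if unresolved:
        raise UnresolvableTaxonError(
            f"species with no genus or family anchor in the tree: {unresolved}"
        )
    for sp, (anchor, pendant) in anchors.items():
        taxon = tree.taxon_namespace.new_taxon(label=sp)
        anchor.new_child(taxon=taxon, edge_length=pendant)
    return tree


def region_diversity(flora: pd.DataFrame, regions: pd.DataFrame, index: TreeIndex) -> pd.DataFrame:
    """Richness and Faith's PD of each region's native flora."""
    native = flora[flora["status"] == "native"]
    masks = {
        rid: index.tip_mask(grp["species_id"])
        for rid, grp in native.groupby("region_id")
    }
    rows = []
    for _, reg in regions.iterrows():
        rid = reg["region_id"]
        mask = masks.get(rid)
        richness = 0 if mask is None else int(mask.sum())
        pd_val = float("nan") if mask is None or not mask.any() else faith_pd(index, mask)
        rows.append(
            {
                "unit_id": rid,
                "unit_type": "region",
                "area_km2": reg["area_km2"],
                "richness": richness,
                "faith_pd": pd_val,
            }
        )
    return pd.DataFrame(rows)


def donor_union_metrics(
    flora: pd.DataFrame,
    regions: pd.DataFrame,
    index: TreeIndex,
    species=None,
) -> pd.DataFrame:
    """Diversity of each species' pooled donor range.

    For each species the donor flora is the union of the native floras of all
    its native regions; the area is the *sum* of those regions' areas.
    """
    native = flora[flora["status"] == "native"]
    area = regions.set_index("region_id")["area_km2"]
    region_masks = {
        rid: index.tip_mask(grp["species_id"]) for rid, grp in native.groupby("region_id")
    }
    donors = native.groupby("species_id")["region_id"].apply(list)
    if species is None:
        species = list(donors.index)
    rows = []
    for sp in species:
        if sp not in donors.index or len(donors[sp]) == 0:
            raise ValueError(f"species {sp!r} has no donor region")
        dset = sorted(set(donors[sp]))
        mask = np.zeros(index.n_tips, dtype=bool)
        for rid in dset:
            mask |= region_masks[rid]
        rows.append(
            {
                "unit_id": sp,
                "unit_type": "donor_union",
                "area_km2": float(area.loc[dset].sum()),
                "richness": int(mask.sum()),
                "faith_pd": faith_pd(index, mask),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class AreaCorrectionFit:
    """OLS fit of log(metric) on log(area) and its scope."""

    metric: str
    slope: float
    intercept: float
    scope: str  # pooled | regions | donor_unions

    def predict_log(self, area_km2) -> np.ndarray:
        return self.intercept + self.slope * np.log(np.asarray(area_km2, dtype=float))


def area_correction(records: pd.DataFrame, metric: str = "faith_pd", scope: str = "pooled"):
    """Residuals of log(metric) ~ log(area) over the pooled diversity records.

    ``scope`` selects which unit types enter the regression ("pooled" fits
    regions and donor unions together — the default — or either alone);
    residuals are returned for every record regardless. Units with a
    non-positive metric are excluded from the fit with a warning (log
    undefined) and get NaN residuals.
    """
    if scope == "pooled":
        fit_rows = records
    elif scope == "regions":
        fit_rows = records[records["unit_type"] == "region"]
    elif scope == "donor_unions":
        fit_rows = records[records["unit_type"] == "donor_union"]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    ok = (fit_rows[metric] > 0) & (fit_rows["area_km2"] > 0)
    if (~ok).any():
        warnings.warn(
            f"excluding {int((~ok).sum())} unit(s) with non-positive {metric} or area "
            "from the area regression"
        )
    fit_rows = fit_rows[ok]
    if len(fit_rows) < 3:
        raise ValueError("area_correction needs at least 3 usable records")
    x = np.log(fit_rows["area_km2"].to_numpy(dtype=float))
    y = np.log(fit_rows[metric].to_numpy(dtype=float))
    slope, intercept = np.polyfit(x, y, 1)
    fit = AreaCorrectionFit(metric=metric, slope=float(slope), intercept=float(intercept), scope=scope)

    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.log(records[metric].to_numpy(dtype=float))
    resid = obs - fit.predict_log(records["area_km2"].to_numpy())
    resid[~np.isfinite(obs)] = np.nan
    return fit, resid
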