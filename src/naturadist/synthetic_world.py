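"""Synthetic macroecological world generator.

Emulates, at configurable scale, the ingredients of a global naturalization
analysis: regions with log-normal areas and continent-clustered centroids on
the sphere; per-cell bioclimatic variables with realistic cross-correlations
and skew driven by latent temperature / precipitation / seasonality fields; a
human-modification index in [0, 1]; an ultrametric phylogeny with genus/family
structure; climatic-niche-driven native floras obeying a species-area power
law; and binary naturalization outcomes drawn from a complementary-log-log
linear predictor with known linear + quadratic coefficients and crossed
species/region random intercepts. Outcomes are strongly imbalanced
(naturalizations are rare), as in real floras.

All randomness flows from per-table child streams of a single seed, so
regenerating one table never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import dendropy

from .phylo import node_depth

__all__ = [
    "DISTANCE_NAMES",
    "TrueParams",
    "WorldConfig",
    "Phylogeny",
    "SyntheticWorld",
    "simulate_phylogeny",
    "simulate_regions",
    "assign_native_floras",
    "generate_outcomes",
    "simulate_world",
]

#: The six donor-recipient distance metrics, in canonical order.
#: pc_temp/pc_prec/hmi/flora_pd are bidirectional (signed, recipient minus
#: donor); phylo_dissim and geo are unidirectional (non-negative).
DISTANCE_NAMES = ("pc_temp", "pc_prec", "hmi", "flora_pd", "phylo_dissim", "geo")

BIDIRECTIONAL = ("pc_temp", "pc_prec", "hmi", "flora_pd")
UNIDIRECTIONAL = ("phylo_dissim", "geo")


@dataclass
class TrueParams:
    """Generative coefficients of the naturalization model (cloglog scale).

    ``beta1``/``beta2`` map each distance name to its linear/quadratic
    coefficient on the scaled (divided by sample SD, not centred) distance.
    ``sigma_species``/``sigma_region`` are the SDs of the crossed random
    intercepts.
    """

    alpha: float = -4.5
    beta1: dict = field(
        default_factory=lambda: {
            "pc_temp": 0.15,
            "pc_prec": 0.53,
            "hmi": 0.39,
            "flora_pd": -1.82,
            "phylo_dissim": -0.45,
            "geo": 0.95,
        }
    )
    beta2: dict = field(
        default_factory=lambda: {
            "pc_temp": -1.32,
            "pc_prec": -0.20,
            "hmi": -0.09,
            "flora_pd": -0.10,
            "phylo_dissim": -0.07,
            "geo": -0.12,
        }
    )
    sigma_species: float = 0.3
    sigma_region: float = 0.3

    def validate(self) -> None:
        if self.sigma_species < 0 or self.sigma_region < 0:
            raise ValueError("random-intercept SDs must be non-negative")
        for name, d in (("beta1", self.beta1), ("beta2", self.beta2)):
            unknown = set(d) - set(DISTANCE_NAMES)
            if unknown:
                raise ValueError(f"unknown distance name(s) in {name}: {sorted(unknown)}")
            missing = set(DISTANCE_NAMES) - set(d)
            if missing:
                raise ValueError(f"{name} missing distance name(s): {sorted(missing)}")


@dataclass
class WorldConfig:
    """Scale and shape knobs of the synthetic world."""

    n_regions: int = 60
    n_cells_per_region: int = 25
    n_species: int = 300
    island_fraction: float = 0.25
    n_continents: int = 5
    area_lognormal_params: tuple = (10.0, 1.2)  # mean/SD of log(km^2)
    niche_breadth: float = 2.0  # in SDs of the regional climate spread
    true_params: TrueParams = field(default_factory=TrueParams)
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_regions", "n_cells_per_region", "n_species", "n_continents"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.island_fraction <= 1.0):
            raise ValueError("island_fraction must lie in [0, 1]")
        if self.niche_breadth <= 0:
            raise ValueError("niche_breadth must be positive")
        self.true_params.validate()


@dataclass
class Phylogeny:
    """Simulated ultrametric tree plus the genus/family label maps of its tips."""

    tree: dendropy.Tree
    genus: dict
    family: dict

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class SyntheticWorld:
    config: WorldConfig
    phylogeny: Phylogeny
    regions: pd.DataFrame
    cells: pd.DataFrame
    flora: pd.DataFrame


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def species_label(i: int) -> str:
    return f"s{i:05d}"


def region_label(i: int) -> str:
    return f"r{i:04d}"


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def simulate_phylogeny(n_species: int, seed: int) -> Phylogeny:
    """Simulate a rooted, ultrametric, binary Yule-style tree.

    Pairs of lineages merge backwards in time at exponentially distributed
    waiting times with rate proportional to the number of extant lineages
    (the pure-birth prior, which spreads branch length evenly over epochs,
    as in large radiations), yielding an ultrametric binary topology with
    positive branch lengths. Tips are labelled ``s00000..``; genus and
    family labels are assigned by cutting the tree at fixed fractions of
    its depth, so congeners form clades.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = _child_rng(seed, 0)
    # (newick fragment, height) per extant lineage
    lineages = [(species_label(i), 0.0) for i in range(n_species)]
    t = 0.0
    while len(lineages) > 1:
        k = len(lineages)
        t += rng.exponential(1.0 / k)
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (na, ha) = lineages[i]
        (nb, hb) = lineages[j]
        merged = (f"({na}:{t - ha:.10f},{nb}:{t - hb:.10f})", t)
        lineages[i] = merged
        del lineages[j]
    newick = lineages[0][0] + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    genus = _clade_labels(tree, cut_fraction=0.25, prefix="g")
    family = _clade_labels(tree, cut_fraction=0.60, prefix="f")
    return Phylogeny(tree=tree, genus=genus, family=family)


def _clade_labels(tree: dendropy.Tree, cut_fraction: float, prefix: str) -> dict:
    """Label tips by the maximal clade whose depth is below a fixed cut."""
    depth = node_depth(tree.seed_node)
    cut = cut_fraction * depth
    labels: dict = {}
    counter = 0

    def visit(node) -> None:
        nonlocal counter
        if node_depth(node) <= cut or node.is_leaf():
            name = f"{prefix}{counter:04d}"
            counter += 1
            for lf in node.leaf_iter():
                labels[lf.taxon.label] = name
        else:
            for ch in node.child_nodes():
                visit(ch)

    visit(tree.seed_node)
    return labels


# ---------------------------------------------------------------------------
# regions, climate grid, HMI
# ---------------------------------------------------------------------------

#: loading of each bioclim variable on (temperature, precipitation,
#: seasonality) latents, plus noise SD and a skew flag (exp-transformed).
_BIOCLIM_SPEC = [
    # (temp, prec, seas, noise, skewed)
    (1.00, 0.05, -0.10, 0.15, False),   # bioclim_1  annual mean temperature
    (0.45, 0.00, 0.55, 0.40, False),    # bioclim_2  diurnal range
    (0.55, 0.10, -0.45, 0.40, False),   # bioclim_3  isothermality
    (-0.25, 0.00, 1.00, 0.20, False),   # bioclim_4  temperature seasonality
    (0.90, 0.00, 0.35, 0.25, False),    # bioclim_5  max temp warmest month
    (0.90, 0.10, -0.40, 0.25, False),   # bioclim_6  min temp coldest month
    (0.10, -0.05, 0.95, 0.30, False),   # bioclim_7  annual range
    (0.80, 0.25, 0.10, 0.35, False),    # bioclim_8  mean temp wettest quarter
    (0.80, -0.20, 0.15, 0.35, False),   # bioclim_9  mean temp driest quarter
    (0.95, 0.00, 0.25, 0.25, False),    # bioclim_10 mean temp warmest quarter
    (0.95, 0.05, -0.30, 0.25, False),   # bioclim_11 mean temp coldest quarter
    (0.10, 1.00, -0.20, 0.20, True),    # bioclim_12 annual precipitation
    (0.10, 0.90, 0.15, 0.30, True),     # bioclim_13 precip wettest month
    (0.05, 0.85, -0.45, 0.30, True),    # bioclim_14 precip driest month
    (-0.05, -0.35, 0.85, 0.35, False),  # bioclim_15 precip seasonality
    (0.10, 0.95, 0.10, 0.25, True),     # bioclim_16 precip wettest quarter
    (0.05, 0.85, -0.40, 0.30, True),    # bioclim_17 precip driest quarter
    (0.30, 0.80, 0.05, 0.35, True),     # bioclim_18 precip warmest quarter
    (-0.10, 0.80, -0.25, 0.35, True),   # bioclim_19 precip coldest quarter
]


def simulate_regions(config: WorldConfig):
    """Draw the region table and the climate/HMI cell grid.

    Returns ``(regions, cells)``. ``cells`` additionally carries the latent
    ``latent_temp``/``latent_prec``/``latent_seas``/``latent_dev`` fields used
    by the generator (handy for tests); the public CSV schema omits them.
    """
    config.validate()
    rng = _child_rng(config.seed, 1)
    nr = config.n_regions
    nc = config.n_cells_per_region

    cont_lat = rng.uniform(-45, 55, size=config.n_continents)
    cont_lon = rng.uniform(-180, 180, size=config.n_continents)
    continent = rng.integers(config.n_continents, size=nr)
    lat = np.clip(cont_lat[continent] + rng.normal(0, 12, nr), -60, 70)
    lon = cont_lon[continent] + rng.normal(0, 15, nr)
    lon = ((lon + 180) % 360) - 180
    mu, sigma = config.area_lognormal_params
    area = rng.lognormal(mu, sigma, size=nr)
    is_island = rng.random(nr) < config.island_fraction

    regions = pd.DataFrame(
        {
            "region_id": [region_label(i) for i in range(nr)],
            "area_km2": area,
            "centroid_lat": lat,
            "centroid_lon": lon,
            "is_island": is_island,
            "continent_id": [f"c{c}" for c in continent],
        }
    )

    # regional latent climate, tied to latitude; development is independent
    temp_r = 22.0 - 0.45 * np.abs(lat) + rng.normal(0, 2.5, nr)
    prec_r = rng.normal(0, 1.0, nr) + 0.6 * np.cos(np.deg2rad(lat))
    seas_r = 0.035 * np.abs(lat) + rng.normal(0, 0.5, nr)
    dev_r = rng.normal(0, 1.0, nr)

    region_idx = np.repeat(np.arange(nr), nc)
    n_cells = nr * nc
    t = temp_r[region_idx] + rng.normal(0, 1.0, n_cells)
    p = prec_r[region_idx] + rng.normal(0, 0.35, n_cells)
    s = seas_r[region_idx] + rng.normal(0, 0.25, n_cells)
    d = dev_r[region_idx] + rng.normal(0, 0.5, n_cells)

    # standardize latents before mixing so loadings act as correlations
    tz = (t - t.mean()) / (t.std() or 1.0)
    pz = (p - p.mean()) / (p.std() or 1.0)
    sz = (s - s.mean()) / (s.std() or 1.0)

    cols = {
        "cell_id": [f"k{i:06d}" for i in range(n_cells)],
        "region_id": [region_label(i) for i in region_idx],
    }
    for v, (lt, lp, ls, noise, skewed) in enumerate(_BIOCLIM_SPEC, start=1):
        z = lt * tz + lp * pz + ls * sz + rng.normal(0, noise, n_cells)
        if skewed:
            z = np.exp(0.9 * z)  # lognormal-style right skew (>1 by construction)
        cols[f"bioclim_{v}"] = z
    hmi = 1.0 / (1.0 + np.exp(-(1.1 * d + 0.25 * tz + rng.normal(0, 0.8, n_cells))))
    cols["hmi"] = hmi
    cells = pd.DataFrame(cols)
    cells["latent_temp"] = t
    cells["latent_prec"] = p
    cells["latent_seas"] = s
    cells["latent_dev"] = d
    return regions, cells


# ---------------------------------------------------------------------------
# native floras
# ---------------------------------------------------------------------------

def assign_native_floras(
    phylogeny: Phylogeny,
    regions: pd.DataFrame,
    cells: pd.DataFrame,
    config: WorldConfig,
) -> pd.DataFrame:
    """Draw climatic-niche-driven native occupancy for every species.

    Each species receives a two-dimensional climatic niche optimum evolved by
    Brownian motion along the phylogeny (so related species have similar
    niches). The probability that a species is native to a region increases
    with region area (species-area effect) and decreases with the squared
    mismatch between the region's climate and the species' optimum, measured
    in units of ``niche_breadth`` regional-SDs. Every species is guaranteed at
    least one native region (its best-matching one).
    """
    config.validate()
    rng = _child_rng(config.seed, 2)
    tips = [lf.taxon.label for lf in phylogeny.tree.leaf_node_iter()]

    clim = cells.groupby("region_id")[["latent_temp", "latent_prec"]].mean()
    clim = clim.loc[regions["region_id"]]
    t_r = clim["latent_temp"].to_numpy()
    p_r = clim["latent_prec"].to_numpy()
    sd_t = t_r.std() or 1.0
    sd_p = p_r.std() or 1.0

    opt = _brownian_tip_states(
        phylogeny.tree, rng,
        root=(t_r.mean(), p_r.mean()),
        tip_sd=(sd_t, sd_p),
    )

    log_area = np.log(regions["area_km2"].to_numpy())
    area_z = (log_area - log_area.mean()) / (log_area.std() or 1.0)

    nb2 = config.niche_breadth ** 2
    rows_region: list = []
    rows_species: list = []
    region_ids = regions["region_id"].to_numpy()
    for sp in tips:
        ot, op = opt[sp]
        mismatch = ((t_r - ot) / sd_t) ** 2 + ((p_r - op) / sd_p) ** 2
        if np.isfinite(nb2):
            eta = -1.6 + 0.9 * area_z - mismatch / (2.0 * nb2)
        else:  # infinite breadth: occupancy independent of climate
            eta = -1.6 + 0.9 * area_z
        prob = 1.0 / (1.0 + np.exp(-eta))
        native = rng.random(len(region_ids)) < prob
        if not native.any():
            native[np.argmin(mismatch)] = True
        idx = np.nonzero(native)[0]
        rows_region.extend(region_ids[idx])
        rows_species.extend([sp] * len(idx))
    return pd.DataFrame(
        {"region_id": rows_region, "species_id": rows_species, "status": "native"}
    )


def _brownian_tip_states(tree: dendropy.Tree, rng, root, tip_sd) -> dict:
    """Brownian motion of a 2-d trait along the tree, scaled to given tip SDs."""
    depth = node_depth(tree.seed_node) or 1.0
    rates = (tip_sd[0] ** 2 / depth, tip_sd[1] ** 2 / depth)
    states: dict = {}
    out: dict = {}
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            states[id(nd)] = np.array(root, dtype=float)
        else:
            el = nd.edge.length or 0.0
            step = rng.normal(0.0, np.sqrt([rates[0] * el + 1e-12, rates[1] * el + 1e-12]))
            states[id(nd)] = states[id(nd.parent_node)] + step
        if nd.is_leaf():
            out[nd.taxon.label] = tuple(states[id(nd)])
    return out


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def generate_outcomes(distance_table: pd.DataFrame, true_params: TrueParams, seed: int) -> pd.DataFrame:
    """Draw naturalization outcomes from the known cloglog model.

    Distances are scaled by their sample SD (no centring) — the same rule the
    fitting stage applies — before the linear predictor
    ``eta = alpha + sum_k beta1_k x_k + beta2_k x_k^2 + u_species + u_region``
    is formed; then ``outcome ~ Bernoulli(1 - exp(-exp(eta)))``.
    """
    true_params.validate()
    rng = _child_rng(seed, 3)
    eta = np.full(len(distance_table), true_params.alpha, dtype=float)
    for name in DISTANCE_NAMES:
        x = distance_table[f"d_{name}"].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"distance d_{name} has zero variance")
        xs = x / sd
        eta += true_params.beta1[name] * xs + true_params.beta2[name] * xs ** 2
    sp_codes, sp_idx = np.unique(distance_table["species_id"], return_inverse=True)
    rg_codes, rg_idx = np.unique(distance_table["recipient_region_id"], return_inverse=True)
    u_sp = rng.normal(0.0, true_params.sigma_species, size=len(sp_codes))
    u_rg = rng.normal(0.0, true_params.sigma_region, size=len(rg_codes))
    eta += u_sp[sp_idx] + u_rg[rg_idx]
    p = -np.expm1(-np.exp(eta))
    outcome = (rng.random(len(eta)) < p).astype(int)
    return pd.DataFrame(
        {
            "species_id": distance_table["species_id"].to_numpy(),
            "recipient_region_id": distance_table["recipient_region_id"].to_numpy(),
            "outcome": outcome,
        }
    )


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate phylogeny, regions/cells and native floras for one config."""
    config.validate()
    phy = simulate_phylogeny(config.n_species, config.seed)
    regions, cells = simulate_regions(config)
    flora = assign_native_floras(phy, regions, cells, config)
    return SyntheticWorld(config=config, phylogeny=phy, regions=regions, cells=cells, flora=flora)
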