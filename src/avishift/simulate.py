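"""Synthetic two-era occupancy studies with known ground truth.

The generator emulates the statistical structure of a continental
breeding-bird atlas comparison: a geographic grid with ecoregion units,
fifty years of monthly climate with a directional warming trend between
two climatic windows, Gaussian-niche species whose era-2 occupancy is
produced cell-by-cell from a known logistic colonisation/extinction
model with dispersal-distance effects and phylogenetically correlated
species intercepts, Dirichlet land-cover mosaics, Brownian-motion traits
on simulated pure-birth trees, and a comparability mask.  Every
downstream input of the pipeline is derivable from the bundle, and
regeneration from (config, seed) is deterministic.
"""

from __future__ import annotations

import json
import random as _pyrandom
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, label as cc_label
from sklearn.cluster import KMeans

from .atlas import OccupancyAtlas, SpeciesRecord, write_atlas, write_roster
from .bioclim import bioclim_for_window
from .rangeshift import great_circle_km
from .sdm import SuitabilitySurface

LANDCOVER_CLASSES = [
    "forest", "shrub", "grassland", "cropland", "wetland",
    "urban", "bare", "water_inland", "sparse",
]

#: three habitat->favourable-class aggregation schemes of increasing breadth
DEFAULT_HABITAT_SCHEMES: list[dict[str, set[str]]] = [
    {h: {h} for h in LANDCOVER_CLASSES},
    {
        "forest": {"forest", "shrub"},
        "shrub": {"shrub", "sparse"},
        "grassland": {"grassland", "cropland"},
        "cropland": {"cropland", "grassland"},
        "wetland": {"wetland", "water_inland"},
        "urban": {"urban", "cropland"},
        "bare": {"bare", "sparse"},
        "water_inland": {"water_inland", "wetland"},
        "sparse": {"sparse", "bare"},
    },
    {
        "forest": {"forest", "shrub", "sparse"},
        "shrub": {"shrub", "grassland", "sparse"},
        "grassland": {"grassland", "cropland", "shrub"},
        "cropland": {"cropland", "grassland", "urban"},
        "wetland": {"wetland", "water_inland", "grassland"},
        "urban": {"urban", "cropland", "grassland"},
        "bare": {"bare", "sparse", "shrub"},
        "water_inland": {"water_inland", "wetland", "bare"},
        "sparse": {"sparse", "bare", "shrub"},
    },
]


@dataclass
class StudyConfig:
    """Conditions of the default synthetic study.

    A 24 x 24 grid of nominal 50-km cells in central Europe, 60 species,
    fifty years of monthly climate with a +1.5 degC warming between the
    1968-1988 and 1997-2017 climatic windows, and event-model
    coefficients giving colonisations a positive baseline-suitability
    effect and a negative distance effect (extinctions mirrored), with
    phylogenetically correlated species intercepts.
    """

    n_lat: int = 24
    n_lon: int = 24
    lat0: float = 40.0
    lon0: float = 10.0
    dlat: float = 0.45
    dlon: float = 0.65
    side_km: float = 50.0
    n_countries: int = 4
    frac_comparable: float = 0.9

    start_year: int = 1968
    end_year: int = 2017
    window1: tuple[int, int] = (1968, 1988)
    window2: tuple[int, int] = (1997, 2017)
    warming_c: float = 1.5  # era2 - era1 mean annual temperature
    precip_trend_frac: float = 0.0  # fractional change in precipitation
    lapse_per_deg_lat: float = 0.8  # degC lost per degree of latitude
    seasonal_amplitude_c: float = 9.0
    spatial_noise_sd_c: float = 1.0
    interannual_sd_c: float = 0.4

    n_species: int = 60
    niche_axes: tuple[str, str] = ("tmean_annual", "prec_annual")
    niche_breadth_frac: tuple[float, float] = (0.35, 0.7)  # x field SD

    # true event-model coefficients on z-scored covariates
    beta_colonisation: tuple[float, float, float, float] = (-2.0, 1.5, 0.75, -1.0)
    beta_extinction: tuple[float, float, float, float] = (-2.0, -1.5, -0.75, 1.0)
    sigma2_species: float = 0.25  # variance of phylogenetic intercepts

    n_trees: int = 10
    birth_rate: float = 1.0
    trait_bm_rate: float = 0.5
    trait_noise_sd: float = 0.2

    n_ecoregion_clusters: int = 10
    n_landcover_hotspots: int = 3


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    grid: pd.DataFrame  # indexed by cell_id
    climate: pd.DataFrame  # long monthly table
    atlas: OccupancyAtlas
    roster: list[SpeciesRecord]
    landcover: dict[str, pd.DataFrame]  # era -> cells x classes fractions
    trees: list[str]  # newick strings
    ground_truth: dict

    @property
    def habitat_schemes(self) -> list[dict[str, set[str]]]:
        return DEFAULT_HABITAT_SCHEMES

    def bioclim(self, window: str = "era1") -> pd.DataFrame:
        cfg = self.config
        win = cfg.window1 if window == "era1" else cfg.window2
        return bioclim_for_window(self.climate, win)

    def true_surfaces(self) -> dict[str, SuitabilitySurface]:
        """Ground-truth suitability surfaces (as if from a perfect SDM)."""
        out = {}
        for sp, info in self.ground_truth["species"].items():
            s1 = np.asarray(info["suitability_era1"])
            s2 = np.asarray(info["suitability_era2"])
            out[sp] = SuitabilitySurface(
                species_id=sp,
                cell_ids=self.grid.index,
                suitability_era1=s1,
                suitability_era2=s2,
                change=s2 - s1,
                weighted_era1=s1,
                weighted_era2=s2,
            )
        return out

    def to_files(self, outdir: str | Path) -> dict[str, str]:
        """Write every pipeline input file plus a ground-truth manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "grid": outdir / "grid.csv",
            "presence": outdir / "presence.csv",
            "climate": outdir / "climate.csv",
            "roster": outdir / "roster.csv",
            "landcover_era1": outdir / "landcover_era1.csv",
            "landcover_era2": outdir / "landcover_era2.csv",
            "manifest": outdir / "manifest.json",
        }
        write_atlas(self.atlas, paths["grid"], paths["presence"])
        self.climate.to_csv(paths["climate"], index=False)
        write_roster(self.roster, paths["roster"])
        for era in ("era1", "era2"):
            self.landcover[era].to_csv(paths[f"landcover_{era}"])
        for i, nwk in enumerate(self.trees):
            p = outdir / f"tree_{i:02d}.nwk"
            p.write_text(nwk + "\n")
            paths[f"tree_{i:02d}"] = p
        manifest = {
            "config": asdict(self.config),
            "seed": self.seed,
            "ground_truth": _manifest_truth(self.ground_truth),
        }
        paths["manifest"].write_text(json.dumps(manifest, indent=1, default=str))
        return {k: str(v) for k, v in paths.items()}


def _manifest_truth(gt: dict) -> dict:
    out = {
        "beta_colonisation": list(gt["beta_colonisation"]),
        "beta_extinction": list(gt["beta_extinction"]),
        "sigma2_species": gt["sigma2_species"],
        "species": {},
    }
    for sp, info in gt["species"].items():
        out["species"][sp] = {
            "niche_optimum": list(info["niche_optimum"]),
            "niche_sd": list(info["niche_sd"]),
            "u_colonisation": info["u_colonisation"],
            "u_extinction": info["u_extinction"],
        }
    return out


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float = 2.0,
                  sd: float = 1.0) -> np.ndarray:
    raw = rng.standard_normal(shape)
    sm = gaussian_filter(raw, sigma=sigma, mode="nearest")
    s = sm.std()
    return sm / (s if s > 0 else 1.0) * sd


def make_grid(config: StudyConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Geographic grid with countries, comparability mask and cell covariates.

    Ecoregion units are attached later (they derive from the climate
    field); countries are contiguous longitude bands; the non-comparable
    cells form spatially clustered patches, emulating regions with
    qualitative historical coverage.
    """
    cfg = config
    ii, jj = np.meshgrid(np.arange(cfg.n_lat), np.arange(cfg.n_lon), indexing="ij")
    lats = cfg.lat0 + (ii.ravel() + 0.5) * cfg.dlat
    lons = cfg.lon0 + (jj.ravel() + 0.5) * cfg.dlon
    n = len(lats)
    cell_ids = [f"c{i:04d}" for i in range(n)]

    band = (jj.ravel() * cfg.n_countries) // cfg.n_lon
    countries = [f"country{b + 1}" for b in band]

    shape = (cfg.n_lat, cfg.n_lon)
    mask_field = _smooth_field(rng, shape, sigma=2.5).ravel()
    cutoff = np.quantile(mask_field, cfg.frac_comparable)
    comparable = mask_field <= cutoff

    alt_field = _smooth_field(rng, shape, sigma=2.0).ravel()
    alt_range = np.clip(600 + 450 * alt_field + rng.normal(0, 80, n), 0, None)
    protected = np.clip(
        cfg.side_km**2 * (0.08 + 0.06 * _smooth_field(rng, shape, 3.0).ravel()
                          + rng.normal(0, 0.02, n)),
        0.0, cfg.side_km**2,
    )
    grid = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "lon": lons,
            "lat": lats,
            "side_km": cfg.side_km,
            "country": countries,
            "comparable": comparable,
            "ecoregion_unit": "pending",
            "alt_range_m": alt_range,
            "protected_km2": protected,
        }
    ).set_index("cell_id")
    return grid


def simulate_climate(
    grid: pd.DataFrame, config: StudyConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Monthly temperature/precipitation series with a linear warming trend.

    Temperature = latitudinal gradient + July-peaked seasonal sinusoid +
    linear trend sized so the two climatic windows differ by
    ``warming_c`` + a smooth spatial random field + interannual noise.
    Precipitation is an exponentiated smooth field with a winter-peaked
    seasonal cycle and its own (default zero) trend.
    """
    cfg = config
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    months = np.arange(1, 13)
    n_cells = len(grid)
    shape = (cfg.n_lat, cfg.n_lon)

    mid1 = (cfg.window1[0] + cfg.window1[1]) / 2.0
    mid2 = (cfg.window2[0] + cfg.window2[1]) / 2.0
    t_slope = cfg.warming_c / (mid2 - mid1)
    p_slope = cfg.precip_trend_frac / (mid2 - mid1)

    lat_mid = grid["lat"].mean()
    t_base = 9.0 - cfg.lapse_per_deg_lat * (grid["lat"].to_numpy() - lat_mid)
    t_spatial = _smooth_field(rng, shape, 2.0, cfg.spatial_noise_sd_c).ravel()
    seasonal = cfg.seasonal_amplitude_c * np.cos(2 * np.pi * (months - 7) / 12.0)

    p_spatial = _smooth_field(rng, shape, 2.0, 0.35).ravel()
    p_base = 55.0 * np.exp(p_spatial + 0.015 * (grid["lat"].to_numpy() - lat_mid))
    p_seasonal = 1.0 + 0.35 * np.cos(2 * np.pi * (months - 1) / 12.0)

    # (cell, year, month) arrays
    t = (
        t_base[:, None, None]
        + seasonal[None, None, :]
        + t_slope * (years - mid1)[None, :, None]
        + t_spatial[:, None, None]
        + rng.normal(0, cfg.interannual_sd_c, (n_cells, len(years), 12))
    )
    p = (
        p_base[:, None, None]
        * p_seasonal[None, None, :]
        * (1.0 + p_slope * (years - mid1))[None, :, None]
        * np.exp(rng.normal(0, 0.15, (n_cells, len(years), 12)))
    )
    p = np.clip(p, 0.0, None)

    idx = pd.MultiIndex.from_product(
        [grid.index, years, months], names=["cell_id", "year", "month"]
    )
    out = pd.DataFrame(
        {"tmean_c": t.ravel(), "prec_mm": p.ravel()}, index=idx
    ).reset_index()
    return out


def assign_ecoregions(
    grid: pd.DataFrame,
    bioclim: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ecoregion units: k-means on location + climate, split by contiguity.

    Each connected component of a climate cluster on the grid becomes a
    separate sampling unit, so units are spatially coherent but a
    cluster can contribute several non-contiguous units.
    """
    cfg = config
    feats = pd.DataFrame(
        {
            "lon": grid["lon"],
            "lat": grid["lat"],
            "tmean": bioclim["tmean_annual"],
            "prec": bioclim["prec_annual"],
        }
    )
    z = (feats - feats.mean()) / feats.std(ddof=0)
    km = KMeans(
        n_clusters=cfg.n_ecoregion_clusters,
        n_init=4,
        random_state=int(rng.integers(0, 2**31 - 1)),
    )
    labels = km.fit_predict(z.to_numpy())
    lab_grid = labels.reshape(cfg.n_lat, cfg.n_lon)
    units = np.empty(lab_grid.shape, dtype=object)
    for c in np.unique(lab_grid):
        comp, n_comp = cc_label(lab_grid == c)
        for k in range(1, n_comp + 1):
            units[comp == k] = f"E{c:02d}_{k:02d}"
    grid = grid.copy()
    grid["ecoregion_unit"] = units.ravel()
    return grid


def simulate_tree_traits(
    n_species: int,
    config: StudyConfig,
    rng: np.random.Generator,
) -> tuple[list[str], "dendropy.Tree", pd.DataFrame]:
    """Pure-birth trees (depth 1) and Brownian traits on the first tree.

    Continuous traits are Brownian motion on the tree plus independent
    noise, mapped through log-normal transforms onto realistic scales;
    categorical traits and flags are drawn with configured frequencies.
    """
    cfg = config
    species = [f"sp{i:03d}" for i in range(n_species)]
    trees: list[dendropy.Tree] = []
    newicks: list[str] = []
    for t in range(cfg.n_trees):
        pyrng = _pyrandom.Random(int(rng.integers(0, 2**31 - 1)))
        tree = dendropy.model.birthdeath.birth_death_tree(
            birth_rate=cfg.birth_rate,
            death_rate=0.0,
            num_extant_tips=n_species,
            rng=pyrng,
        )
        depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                edge.length /= depth
        for leaf, sp in zip(tree.leaf_node_iter(), species):
            leaf.taxon.label = sp
        trees.append(tree)
        newicks.append(tree.as_string(schema="newick", suppress_rooting=True).strip())

    from .glmm import phylo_correlation  # deferred: avoids cycle at import time

    A = phylo_correlation(trees[0], species).matrix
    L = np.linalg.cholesky(A + 1e-8 * np.eye(n_species))

    def bm(scale: float) -> np.ndarray:
        return scale * (L @ rng.standard_normal(n_species)) + rng.normal(
            0, cfg.trait_noise_sd, n_species
        )

    mass = np.exp(3.5 + 1.2 * bm(cfg.trait_bm_rate))
    genlen = np.exp(1.2 + 0.3 * bm(cfg.trait_bm_rate))
    clutch = np.clip(np.exp(1.4 + 0.4 * bm(cfg.trait_bm_rate)), 1.0, None)
    hwi = np.clip(25 + 10 * bm(cfg.trait_bm_rate), 5.0, None)
    diet = np.clip(1.0 + 0.5 * bm(cfg.trait_bm_rate), 0.05, np.log(10))
    habitat_breadth = np.clip(1.0 + 0.4 * bm(cfg.trait_bm_rate), 0.1, None)
    migration = rng.choice(["resident", "short", "long"], size=n_species,
                           p=[0.5, 0.3, 0.2])
    habitat = rng.choice(LANDCOVER_CLASSES[:6], size=n_species)
    traits = pd.DataFrame(
        {
            "species_id": species,
            "body_mass_g": mass,
            "generation_length_yr": genlen,
            "clutch_size": clutch,
            "hand_wing_index": hwi,
            "diet_breadth": diet,
            "habitat_breadth": habitat_breadth,
            "migration_status": migration,
            "primary_habitat": habitat,
            "introduced": rng.random(n_species) < 0.05,
            "irregular_breeder": rng.random(n_species) < 0.05,
            "marine": rng.random(n_species) < 0.03,
            "montane": rng.random(n_species) < 0.10,
            "annex1_or_persecuted": rng.random(n_species) < 0.15,
        }
    ).set_index("species_id")
    return newicks, trees[0], traits


def _gaussian_suitability(
    bioclim: pd.DataFrame, axes: tuple[str, ...], optimum: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    z = (bioclim[list(axes)].to_numpy() - optimum[None, :]) / sd[None, :]
    return np.exp(-0.5 * (z**2).sum(axis=1))


def _zscore(x: np.ndarray) -> np.ndarray:
    s = x.std(ddof=0)
    return (x - x.mean()) / (s if s > 0 else 1.0)


def simulate_species(
    grid: pd.DataFrame,
    bio1: pd.DataFrame,
    bio2: pd.DataFrame,
    config: StudyConfig,
    rng: np.random.Generator,
    A: np.ndarray,
    species: list[str],
) -> tuple[OccupancyAtlas, dict]:
    """Occupancy for both eras from Gaussian niches + a known event model.

    Era-1 presence is Bernoulli in the era-1 niche suitability.  Era-2
    presence is built cell-wise: unoccupied cells colonise with
    probability logistic(b0 + b1 z(s1) + b2 z(ds) + b3 z(dist) + u_s),
    occupied cells go extinct with the extinction coefficient set,
    where dist is the distance to the nearest era-1-occupied cell and
    u_s are phylogenetically correlated species intercepts.
    """
    cfg = config
    n_cells = len(grid)
    lons = grid["lon"].to_numpy()
    lats = grid["lat"].to_numpy()
    L = np.linalg.cholesky(A + 1e-8 * np.eye(len(species)))
    sd_u = np.sqrt(cfg.sigma2_species)
    u_col = sd_u * (L @ rng.standard_normal(len(species)))
    u_ext = sd_u * (L @ rng.standard_normal(len(species)))

    axes = cfg.niche_axes
    field_mean = bio1[list(axes)].mean().to_numpy()
    field_sd = bio1[list(axes)].std(ddof=0).to_numpy()

    bc = np.asarray(cfg.beta_colonisation)
    be = np.asarray(cfg.beta_extinction)

    presence = {}
    truth_species = {}
    for si, sp in enumerate(species):
        for _ in range(50):  # redraw niches leaving too-small ranges
            optimum = field_mean + field_sd * rng.uniform(-1.2, 1.2, len(axes))
            breadth = field_sd * rng.uniform(*cfg.niche_breadth_frac, size=len(axes))
            s1 = _gaussian_suitability(bio1, axes, optimum, breadth)
            p1 = rng.random(n_cells) < s1
            if p1.sum() >= 8:
                break
        s2 = _gaussian_suitability(bio2, axes, optimum, breadth)

        occ_idx = np.flatnonzero(p1)
        d = great_circle_km(
            lons[:, None], lats[:, None], lons[None, occ_idx], lats[None, occ_idx]
        )
        d_self = d.copy()
        d_self[occ_idx, np.arange(len(occ_idx))] = np.inf  # exclude self
        dist_nearest = np.where(p1, d_self[:, :].min(axis=1), d.min(axis=1))

        zs1 = _zscore(s1)
        zds = _zscore(s2 - s1)
        zd = _zscore(dist_nearest)

        eta_col = bc[0] + bc[1] * zs1 + bc[2] * zds + bc[3] * zd + u_col[si]
        eta_ext = be[0] + be[1] * zs1 + be[2] * zds + be[3] * zd + u_ext[si]
        p_col = 1.0 / (1.0 + np.exp(-eta_col))
        p_ext = 1.0 / (1.0 + np.exp(-eta_ext))
        draw = rng.random(n_cells)
        p2 = np.where(p1, draw >= p_ext, draw < p_col)

        presence[(sp, "era1")] = p1
        presence[(sp, "era2")] = p2
        truth_species[sp] = {
            "niche_optimum": optimum.tolist(),
            "niche_sd": breadth.tolist(),
            "suitability_era1": s1,
            "suitability_era2": s2,
            "u_colonisation": float(u_col[si]),
            "u_extinction": float(u_ext[si]),
        }

    cols = pd.MultiIndex.from_tuples(sorted(presence), names=["species_id", "era"])
    mat = pd.DataFrame(
        {key: presence[key] for key in sorted(presence)}, index=grid.index
    )
    mat.columns = cols
    atlas = OccupancyAtlas(grid=grid, presence=mat)
    truth = {
        "beta_colonisation": cfg.beta_colonisation,
        "beta_extinction": cfg.beta_extinction,
        "sigma2_species": cfg.sigma2_species,
        "species": truth_species,
    }
    return atlas, truth


def simulate_landcover(
    grid: pd.DataFrame, config: StudyConfig, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    """Dirichlet land-cover mosaics per era with smooth spatial preference.

    Era-2 fractions are the era-1 fractions perturbed by small
    log-normal factors and renormalised, giving modest, spatially
    correlated cover change.
    """
    cfg = config
    shape = (cfg.n_lat, cfg.n_lon)
    n = len(grid)
    k = len(LANDCOVER_CLASSES)
    pref = np.stack(
        [_smooth_field(rng, shape, 2.5).ravel() for _ in range(k)], axis=1
    )
    alpha = np.exp(1.0 + 0.8 * pref)
    era1 = np.stack([rng.dirichlet(alpha[i]) for i in range(n)])
    drift = np.exp(
        np.stack([_smooth_field(rng, shape, 3.0, 0.25).ravel() for _ in range(k)], axis=1)
    )
    era2 = era1 * drift
    era2 = era2 / era2.sum(axis=1, keepdims=True)
    return {
        "era1": pd.DataFrame(era1, index=grid.index, columns=LANDCOVER_CLASSES),
        "era2": pd.DataFrame(era2, index=grid.index, columns=LANDCOVER_CLASSES),
    }


def generate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Build a complete synthetic study from one root seed.

    Component seeds are split from the root via ``SeedSequence.spawn``
    so that each part (grid, climate, trees, species, land cover) has an
    independent, reproducible stream.
    """
    cfg = config or StudyConfig()
    streams = np.random.SeedSequence(seed).spawn(6)
    rng_grid, rng_clim, rng_tree, rng_sp, rng_lc, rng_eco = (
        np.random.default_rng(s) for s in streams
    )

    grid = make_grid(cfg, rng_grid)
    climate = simulate_climate(grid, cfg, rng_clim)
    bio1 = bioclim_for_window(climate, cfg.window1)
    bio2 = bioclim_for_window(climate, cfg.window2)
    grid = assign_ecoregions(grid, bio1, cfg, rng_eco)

    newicks, tree0, traits = simulate_tree_traits(cfg.n_species, cfg, rng_tree)
    species = list(traits.index)

    from .glmm import phylo_correlation

    A = phylo_correlation(tree0, species).matrix
    atlas, truth = simulate_species(grid, bio1, bio2, cfg, rng_sp, A, species)
    landcover = simulate_landcover(grid, cfg, rng_lc)

    roster = []
    for sp in species:
        row = traits.loc[sp]
        roster.append(
            SpeciesRecord(
                species_id=sp,
                introduced=bool(row["introduced"]),
                irregular_breeder=bool(row["irregular_breeder"]),
                marine=bool(row["marine"]),
                montane=bool(row["montane"]),
                annex1_or_persecuted=bool(row["annex1_or_persecuted"]),
                body_mass_g=float(row["body_mass_g"]),
                generation_length_yr=float(row["generation_length_yr"]),
                clutch_size=float(row["clutch_size"]),
                hand_wing_index=float(row["hand_wing_index"]),
                migration_status=str(row["migration_status"]),
                diet_breadth=float(row["diet_breadth"]),
                habitat_breadth=float(row["habitat_breadth"]),
                primary_habitat=str(row["primary_habitat"]),
                range_size_cells_era1=atlas.range_size(sp, "era1"),
            )
        )

    truth["seed"] = seed
    return SyntheticStudy(
        config=cfg,
        seed=seed,
        grid=grid,
        climate=climate,
        atlas=atlas,
        roster=roster,
        landcover=landcover,
        trees=newicks,
        ground_truth=truth,
    )
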