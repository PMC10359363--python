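"""Colonisation/extinction event extraction and model-table assembly.

Each species x comparable-cell combination falls into one of four
states between the eras: colonisation (absent then present), extinction
(present then absent), continually occupied, or never occupied.
Successes (events) are paired with an equal number of sampled failures
(never-occupied cells for colonisation, continually occupied cells for
extinction; optionally weighted by 1/distance to the nearest continually
occupied cell), and each row receives the environmental and trait
covariates before a final z-transformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import OccupancyAtlas, SpeciesRecord
from .rangeshift import CentreOfGravity, centre_of_gravity, great_circle_km

logger = logging.getLogger(__name__)

STATUSES = ("colonisation", "extinction", "continual", "never")

#: continuous covariates subject to the z-transformation
CONTINUOUS_COVARIATES = [
    "suit_baseline",
    "suit_change",
    "favourable_cover_baseline",
    "favourable_cover_change",
    "habitat_diversity",
    "alt_range",
    "protected_area",
    "dist_nearest_continual_km",
    "dist_to_cog_km",
    "body_mass_g",
    "generation_length_yr",
    "clutch_size",
    "hand_wing_index",
    "diet_breadth",
    "range_size_cells_era1",
]


def classify_cells(atlas: OccupancyAtlas, species_id: str) -> pd.DataFrame:
    """Per-cell dynamic status for one species from the 2x2 truth table."""
    p1 = atlas.presence_vector(species_id, "era1")
    p2 = atlas.presence_vector(species_id, "era2")
    status = np.where(
        p1 & p2, "continual",
        np.where(p1 & ~p2, "extinction", np.where(~p1 & p2, "colonisation", "never")),
    )
    return pd.DataFrame({"cell_id": atlas.cell_ids, "status": status})


def dist_nearest_continual(
    grid: pd.DataFrame, continual_cells: list[str], target_cells: list[str]
) -> pd.Series:
    """Great-circle km from each target centroid to the nearest continually
    occupied cell centroid.  Undefined (raises) for an empty continual set:
    the caller excludes such species from distance-dependent models."""
    if len(continual_cells) == 0:
        raise ValueError("empty continually-occupied set: distance undefined")
    tl = grid.loc[target_cells]
    cl = grid.loc[continual_cells]
    d = great_circle_km(
        tl["lon"].to_numpy()[:, None],
        tl["lat"].to_numpy()[:, None],
        cl["lon"].to_numpy()[None, :],
        cl["lat"].to_numpy()[None, :],
    )
    # a target that is itself continually occupied measures its isolation
    # from the nearest *other* continual cell, never the trivial zero
    cpos = {c: j for j, c in enumerate(continual_cells)}
    for i, t in enumerate(tl.index):
        if t in cpos:
            d[i, cpos[t]] = np.inf
    out = pd.Series(d.min(axis=1), index=tl.index)
    if np.isinf(out).any():
        raise ValueError("a target's only continual cell is itself: distance undefined")
    return out


def dist_to_cog(cog: CentreOfGravity, grid: pd.DataFrame, cells: list[str]) -> pd.Series:
    """Great-circle km from each cell centroid to a species' era-1 COG."""
    sub = grid.loc[cells]
    d = great_circle_km(
        sub["lon"].to_numpy(), sub["lat"].to_numpy(), cog.lon, cog.lat
    )
    return pd.Series(d, index=sub.index)


def shannon_diversity(proportions: np.ndarray) -> float:
    """H = -sum p ln p with 0 ln 0 := 0; proportions must sum to 1."""
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("negative proportions")
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError(f"proportions sum to {p.sum():.6f}, not 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def favourable_cover(
    landcover_era1: pd.DataFrame,
    landcover_era2: pd.DataFrame,
    primary_habitat: str,
    schemes: list[dict[str, set[str]]],
) -> tuple[pd.Series, pd.Series]:
    """Baseline fraction of favourable land cover per cell, and its change.

    Each aggregation scheme maps a habitat label to the set of cover
    classes counted as favourable; results are averaged across schemes.
    A habitat mapping to zero classes contributes zeros, with a warning.
    """
    baselines, changes = [], []
    for scheme in schemes:
        classes = [
            c for c in scheme.get(primary_habitat, set()) if c in landcover_era1.columns
        ]
        if not classes:
            warnings.warn(
                f"habitat {primary_habitat!r} maps to no land-cover classes in a scheme"
            )
            baselines.append(pd.Series(0.0, index=landcover_era1.index))
            changes.append(pd.Series(0.0, index=landcover_era1.index))
            continue
        b = landcover_era1[classes].sum(axis=1)
        a = landcover_era2[classes].sum(axis=1)
        baselines.append(b)
        changes.append(a - b)
    n = len(schemes)
    return sum(baselines) / n, sum(changes) / n


def sample_failures(
    events: pd.DataFrame,
    grid: pd.DataFrame,
    n_successes: int,
    mode: str,
    weighting: str = "uniform",
    seed: int | None = None,
) -> list[str]:
    """Sample failure cells matched to the success count, without replacement.

    Colonisation failures come from never-occupied cells, extinction
    failures from continually occupied cells.  ``inverse_distance``
    weighting (colonisation only, per the sampling design) draws with
    probability proportional to 1/distance-to-nearest-continual.  If the
    pool is smaller than the success count the whole pool is returned
    with a warning.
    """
    if mode not in ("colonisation", "extinction"):
        raise ValueError(f"mode {mode!r}")
    if n_successes == 0:
        raise ValueError("species has no events of this type")
    pool_status = "never" if mode == "colonisation" else "continual"
    pool = events.loc[events["status"] == pool_status, "cell_id"].tolist()
    if not pool:
        raise ValueError(f"no candidate failure cells with status {pool_status!r}")
    n_draw = min(n_successes, len(pool))
    if n_draw < n_successes:
        warnings.warn(
            f"failure pool ({len(pool)}) smaller than success count ({n_successes})"
        )
    rng = np.random.default_rng(seed)
    if weighting == "uniform":
        idx = rng.choice(len(pool), size=n_draw, replace=False)
    elif weighting == "inverse_distance":
        continual = events.loc[events["status"] == "continual", "cell_id"].tolist()
        d = dist_nearest_continual(grid, continual, pool)
        w = 1.0 / np.maximum(d.to_numpy(), 1e-9)
        idx = rng.choice(len(pool), size=n_draw, replace=False, p=w / w.sum())
    else:
        raise ValueError(f"weighting {weighting!r}")
    return [pool[i] for i in sorted(idx)]


@dataclass
class SpeciesEventData:
    """Per-species ingredients reused across absence resamples."""

    species_id: str
    events: pd.DataFrame
    continual_cells: list[str]
    cog_era1: CentreOfGravity


def prepare_species(atlas: OccupancyAtlas, species_id: str) -> SpeciesEventData:
    events = classify_cells(atlas, species_id)
    continual = events.loc[events["status"] == "continual", "cell_id"].tolist()
    p1 = atlas.presence_vector(species_id, "era1").astype(float)
    cog = centre_of_gravity(
        atlas.grid["lon"].to_numpy(), atlas.grid["lat"].to_numpy(), p1
    )
    return SpeciesEventData(species_id, events, continual, cog)


def assemble_table(
    atlas: OccupancyAtlas,
    roster: dict[str, SpeciesRecord],
    surfaces: dict[str, "object"],
    landcover_era1: pd.DataFrame,
    landcover_era2: pd.DataFrame,
    habitat_schemes: list[dict[str, set[str]]],
    mode: str,
    weighting: str = "uniform",
    seed: int | None = None,
    z_scale: bool = True,
    include_distances: bool = True,
) -> pd.DataFrame:
    """One success/failure row per cell with the full covariate set.

    Species without events of the requested type, without continually
    occupied cells (distance covariates undefined), or with missing
    mandatory traits are excluded (counts logged).  Continuous
    covariates are z-scored over the assembled table; a zero-variance
    column is a hard error naming the column.
    """
    grid = atlas.grid
    diversity = pd.Series(
        [shannon_diversity(row / row.sum()) for _, row in landcover_era1.iterrows()],
        index=landcover_era1.index,
    )
    rng = np.random.default_rng(seed)
    rows = []
    n_skipped = {"no_events": 0, "no_continual": 0, "missing_traits": 0}
    for sp, rec in sorted(roster.items()):
        if sp not in surfaces:
            continue
        trait_vals = {
            "body_mass_g": rec.body_mass_g,
            "generation_length_yr": rec.generation_length_yr,
            "clutch_size": rec.clutch_size,
            "hand_wing_index": rec.hand_wing_index,
            "diet_breadth": rec.diet_breadth,
            "range_size_cells_era1": rec.range_size_cells_era1,
        }
        if any(v is None or (isinstance(v, float) and np.isnan(v)) for v in trait_vals.values()):
            n_skipped["missing_traits"] += 1
            continue
        data = prepare_species(atlas, sp)
        successes = data.events.loc[data.events["status"] == mode, "cell_id"].tolist()
        if not successes:
            n_skipped["no_events"] += 1
            continue
        if not data.continual_cells:
            n_skipped["no_continual"] += 1
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        failures = sample_failures(
            data.events, grid, len(successes), mode, weighting, seed=sub_seed
        )
        surf = surfaces[sp]
        suit1 = pd.Series(surf.suitability_era1, index=surf.cell_ids)
        suitd = pd.Series(surf.change, index=surf.cell_ids)
        fav_base, fav_change = favourable_cover(
            landcover_era1, landcover_era2, rec.primary_habitat, habitat_schemes
        )
        if mode == "extinction" and len(data.continual_cells) < 2:
            n_skipped["no_continual"] += 1
            continue
        for response, cells in ((1, successes), (0, failures)):
            dists = dist_nearest_continual(grid, data.continual_cells, cells)
            cog_d = dist_to_cog(data.cog_era1, grid, cells)
            for cell in cells:
                rows.append(
                    {
                        "response": response,
                        "species_id": sp,
                        "cell_id": cell,
                        "country": grid.loc[cell, "country"],
                        "suit_baseline": suit1.loc[cell],
                        "suit_change": suitd.loc[cell],
                        "favourable_cover_baseline": fav_base.loc[cell],
                        "favourable_cover_change": fav_change.loc[cell],
                        "habitat_diversity": diversity.loc[cell],
                        "alt_range": grid.loc[cell, "alt_range_m"],
                        "protected_area": grid.loc[cell, "protected_km2"],
                        "dist_nearest_continual_km": float(dists.loc[cell]),
                        "dist_to_cog_km": float(cog_d.loc[cell]),
                        "migration_status": rec.migration_status,
                        "annex1_or_persecuted": int(rec.annex1_or_persecuted),
                        "montane": int(rec.montane),
                        **trait_vals,
                    }
                )
    if n_skipped["no_events"] or n_skipped["no_continual"] or n_skipped["missing_traits"]:
        logger.info("species skipped: %s", n_skipped)
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError(f"no species yielded {mode} rows")
    if not include_distances:
        table = table.drop(columns=["dist_nearest_continual_km", "dist_to_cog_km"])
    if z_scale:
        for col in CONTINUOUS_COVARIATES:
            if col not in table.columns:
                continue
            x = table[col].astype(float)
            sd = x.std(ddof=0)
            if sd == 0:
                raise ValueError(f"covariate {col!r} has zero variance; cannot z-scale")
            table[col] = (x - x.mean()) / sd
    return table
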