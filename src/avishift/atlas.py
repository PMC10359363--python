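"""Two-era occupancy atlases on a 50-km grid.

An atlas pairs a grid table (cell centroids, country labels, a
sampling-effort comparability flag, ecoregion unit labels and the
per-cell covariates that do not depend on species) with a long-format
presence table recording, for every species and era, the grid cells in
which breeding was confirmed.  Eras are always exactly two: ``era1``
(the historical survey) and ``era2`` (the modern resurvey).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ERAS = ("era1", "era2")

GRID_COLUMNS = [
    "cell_id",
    "lon",
    "lat",
    "side_km",
    "country",
    "comparable",
    "ecoregion_unit",
    "alt_range_m",
    "protected_km2",
]

PRESENCE_COLUMNS = ["species_id", "cell_id", "era", "present"]

ROSTER_COLUMNS = [
    "species_id",
    "introduced",
    "irregular_breeder",
    "marine",
    "montane",
    "annex1_or_persecuted",
    "body_mass_g",
    "generation_length_yr",
    "clutch_size",
    "hand_wing_index",
    "migration_status",
    "diet_breadth",
    "habitat_breadth",
    "primary_habitat",
    "range_size_cells_era1",
]


class AtlasError(ValueError):
    """Raised for schema or referential-integrity violations."""


@dataclass
class SpeciesRecord:
    """Roster entry: exclusion flags plus the trait set used downstream.

    ``diet_breadth`` is a Shannon index of proportional diet-category
    use; ``hand_wing_index`` is the usual dispersal proxy.  Missing
    traits are ``None``/NaN and are handled by listwise exclusion when
    the model table is assembled.
    """

    species_id: str
    introduced: bool = False
    irregular_breeder: bool = False
    marine: bool = False
    montane: bool = False
    annex1_or_persecuted: bool = False
    body_mass_g: float | None = None
    generation_length_yr: float | None = None
    clutch_size: float | None = None
    hand_wing_index: float | None = None
    migration_status: str | None = None
    diet_breadth: float | None = None
    habitat_breadth: float | None = None
    primary_habitat: str | None = None
    range_size_cells_era1: int | None = None


@dataclass
class OccupancyAtlas:
    """Grid table plus a wide boolean presence matrix.

    ``grid`` is indexed by ``cell_id``; ``presence`` is indexed by
    ``cell_id`` with a (species_id, era) column MultiIndex.  Absent
    combinations are False.
    """

    grid: pd.DataFrame
    presence: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.grid.index.name != "cell_id":
            if "cell_id" not in self.grid.columns:
                raise AtlasError("grid table must carry a cell_id column")
            self.grid = self.grid.set_index("cell_id")
        if not self.grid.index.is_unique:
            dup = self.grid.index[self.grid.index.duplicated()][0]
            raise AtlasError(f"duplicate cell_id {dup!r} in grid table")
        bad = self.grid["protected_km2"] > self.grid["side_km"] ** 2
        if bad.any():
            raise AtlasError(
                f"protected_km2 exceeds cell area for {self.grid.index[bad][0]!r}"
            )
        if (self.grid["alt_range_m"] < 0).any():
            raise AtlasError("negative altitudinal range")
        if self.presence.empty:
            self.presence = pd.DataFrame(
                index=self.grid.index,
                columns=pd.MultiIndex.from_arrays([[], []], names=["species_id", "era"]),
                dtype=bool,
            )
        self.presence = self.presence.reindex(self.grid.index, fill_value=False)

    # -- basic queries -------------------------------------------------

    @property
    def cell_ids(self) -> pd.Index:
        return self.grid.index

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.presence.columns.get_level_values("species_id").unique())

    def is_present(self, species_id: str, cell_id: str, era: str) -> bool:
        if (species_id, era) not in self.presence.columns:
            return False
        return bool(self.presence.loc[cell_id, (species_id, era)])

    def occupied_cells(self, species_id: str, era: str) -> pd.Index:
        if (species_id, era) not in self.presence.columns:
            return self.grid.index[:0]
        col = self.presence[(species_id, era)]
        return col.index[col.to_numpy(dtype=bool)]

    def range_size(self, species_id: str, era: str) -> int:
        """Number of occupied grid cells for one species in one era."""
        return int(len(self.occupied_cells(species_id, era)))

    def presence_vector(self, species_id: str, era: str) -> np.ndarray:
        """Boolean occupancy over ``self.cell_ids`` order."""
        if (species_id, era) not in self.presence.columns:
            return np.zeros(len(self.grid), dtype=bool)
        return self.presence[(species_id, era)].to_numpy(dtype=bool)


def _as_bool(series: pd.Series, name: str) -> pd.Series:
    if series.dtype == bool:
        return series
    mapped = series.astype(str).str.strip().str.lower().map(
        {"1": True, "0": False, "true": True, "false": False}
    )
    if mapped.isna().any():
        raise AtlasError(f"column {name!r} contains values that are not 0/1 booleans")
    return mapped.astype(bool)


def read_grid(path: str | Path) -> pd.DataFrame:
    grid = pd.read_csv(path)
    missing = set(GRID_COLUMNS) - set(grid.columns)
    if missing:
        raise AtlasError(f"grid table missing columns: {sorted(missing)}")
    grid["comparable"] = _as_bool(grid["comparable"], "comparable")
    grid["cell_id"] = grid["cell_id"].astype(str)
    return grid


def read_atlas(grid_path: str | Path, presence_path: str | Path) -> OccupancyAtlas:
    """Load a grid table and long-format presence table into an atlas.

    Unlisted (species, cell, era) triples default to absent.  A presence
    row naming an unknown cell, era, or contradicting another row is a
    hard error identifying the offending record.
    """
    grid = read_grid(grid_path)
    pres = pd.read_csv(presence_path, dtype={"species_id": str, "cell_id": str})
    missing = set(PRESENCE_COLUMNS) - set(pres.columns)
    if missing:
        raise AtlasError(f"presence table missing columns: {sorted(missing)}")

    known = set(grid["cell_id"])
    unknown = ~pres["cell_id"].isin(known)
    if unknown.any():
        row = pres.index[unknown][0]
        raise AtlasError(
            f"presence row {row} references unknown cell_id {pres.loc[row, 'cell_id']!r}"
        )
    bad_era = ~pres["era"].isin(ERAS)
    if bad_era.any():
        row = pres.index[bad_era][0]
        raise AtlasError(f"presence row {row} has era {pres.loc[row, 'era']!r}")
    pres["present"] = _as_bool(pres["present"], "present")

    key = ["species_id", "cell_id", "era"]
    grouped = pres.groupby(key)["present"].nunique()
    if (grouped > 1).any():
        triple = grouped.index[grouped > 1][0]
        raise AtlasError(f"contradictory presence rows for {triple}")
    pres = pres.drop_duplicates(subset=key)

    wide = (
        pres[pres["present"]]
        .assign(value=True)
        .pivot_table(
            index="cell_id",
            columns=["species_id", "era"],
            values="value",
            aggfunc="any",
            fill_value=False,
        )
        .astype(bool)
    )
    atlas = OccupancyAtlas(grid=grid, presence=wide)
    return atlas


def write_atlas(
    atlas: OccupancyAtlas, grid_path: str | Path, presence_path: str | Path
) -> None:
    """Write the grid and the True presence triples back to CSV."""
    atlas.grid.reset_index().to_csv(grid_path, index=False, columns=GRID_COLUMNS)
    stacked = atlas.presence.stack(["species_id", "era"], future_stack=True)
    stacked = stacked[stacked].reset_index()
    stacked.columns = ["cell_id", "species_id", "era", "present"]
    stacked["present"] = 1
    stacked = stacked.sort_values(["species_id", "cell_id", "era"])
    stacked.to_csv(presence_path, index=False, columns=PRESENCE_COLUMNS)


def read_roster(path: str | Path) -> list[SpeciesRecord]:
    tab = pd.read_csv(path, dtype={"species_id": str})
    missing = set(ROSTER_COLUMNS) - set(tab.columns)
    if missing:
        raise AtlasError(f"roster table missing columns: {sorted(missing)}")
    records = []
    for _, row in tab.iterrows():
        kwargs = {}
        for col in ROSTER_COLUMNS:
            val = row[col]
            if col in (
                "introduced",
                "irregular_breeder",
                "marine",
                "montane",
                "annex1_or_persecuted",
            ):
                val = bool(int(val)) if not isinstance(val, (bool, np.bool_)) else bool(val)
            elif pd.isna(val):
                val = None
            kwargs[col] = val
        records.append(SpeciesRecord(**kwargs))
    return records


def write_roster(roster: Sequence[SpeciesRecord], path: str | Path) -> None:
    rows = []
    for rec in roster:
        row = {col: getattr(rec, col) for col in ROSTER_COLUMNS}
        for col in (
            "introduced",
            "irregular_breeder",
            "marine",
            "montane",
            "annex1_or_persecuted",
        ):
            row[col] = int(row[col])
        rows.append(row)
    pd.DataFrame(rows, columns=ROSTER_COLUMNS).to_csv(path, index=False)


# -- masking and roster filtering --------------------------------------


def apply_study_mask(atlas: OccupancyAtlas, use_comparable_only: bool = True) -> OccupancyAtlas:
    """Restrict an atlas to sampling-effort-comparable cells.

    With ``use_comparable_only=False`` this is the identity.  Removing
    every cell is a hard error (an all-incomparable atlas cannot support
    any downstream analysis).
    """
    if not use_comparable_only:
        return atlas
    keep = atlas.grid["comparable"].to_numpy(dtype=bool)
    if not keep.any():
        raise AtlasError("study mask removes every grid cell")
    return OccupancyAtlas(
        grid=atlas.grid.loc[keep].copy(), presence=atlas.presence.loc[keep].copy()
    )


def filter_roster(
    atlas: OccupancyAtlas,
    roster: Iterable[SpeciesRecord],
    min_cells: int = 5,
    min_cells_era: str = "any",
) -> list[str]:
    """Apply the standard roster exclusions.

    Retains species that are not introduced, not irregular breeders, not
    marine, and occupy at least ``min_cells`` grid cells.  The era the
    cell-count threshold applies to is configurable (``any`` keeps a
    species reaching the threshold in either era; ``era1``/``era2``/
    ``both`` restrict it).
    """
    if min_cells_era not in ("any", "era1", "era2", "both"):
        raise ValueError(f"min_cells_era {min_cells_era!r}")
    kept = []
    for rec in roster:
        if rec.introduced or rec.irregular_breeder or rec.marine:
            continue
        n1 = atlas.range_size(rec.species_id, "era1")
        n2 = atlas.range_size(rec.species_id, "era2")
        ok = {
            "any": n1 >= min_cells or n2 >= min_cells,
            "era1": n1 >= min_cells,
            "era2": n2 >= min_cells,
            "both": n1 >= min_cells and n2 >= min_cells,
        }[min_cells_era]
        if ok:
            kept.append(rec.species_id)
    if not kept:
        raise AtlasError("roster filter retained no species")
    return kept


def study_area_km2(atlas: OccupancyAtlas) -> float:
    """Total study area: sum of squared cell side lengths."""
    return float((atlas.grid["side_km"] ** 2).sum())


def range_change_summary(
    atlas: OccupancyAtlas, species_ids: Iterable[str], threshold: float = 0.05
) -> pd.DataFrame:
    """Fractional range change per species with >threshold expansion flags.

    Change is (n2 - n1)/n1 over the atlas' cells; species with n1 = 0
    are excluded (undefined ratio).
    """
    rows = []
    for sp in species_ids:
        n1 = atlas.range_size(sp, "era1")
        n2 = atlas.range_size(sp, "era2")
        if n1 == 0:
            continue
        change = (n2 - n1) / n1
        rows.append(
            {
                "species_id": sp,
                "n_era1": n1,
                "n_era2": n2,
                "change": change,
                "expanded": change > threshold,
                "contracted": change < -threshold,
            }
        )
    return pd.DataFrame(rows)
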