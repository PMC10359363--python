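"""High-level pipeline drivers tying the modules together.

These functions wire the canonical analysis path: mask the atlas to
comparable cells, filter the roster, build the event-model table from
suitability surfaces, and fit the phylogenetic mixed model — the same
sequence a study of two-era atlas dynamics runs end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import atlas as atlas_io
from . import events, glmm, sdm
from .simulate import StudyConfig, SyntheticStudy

#: the environmental + trait fixed effects of the full event model
FULL_FIXED_EFFECTS = [
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
    "migration_status",
    "annex1_or_persecuted",
    "montane",
]

#: the covariates of the generative event model (for recovery checks)
CORE_FIXED_EFFECTS = ["suit_baseline", "suit_change", "dist_nearest_continual_km"]

#: study conditions for the distance-ablation contrast: dispersal distance
#: dominates the event model, the regime in which removing the distance
#: covariates must visibly degrade the fixed-effect fit
DISTANCE_DRIVEN_CONFIG = StudyConfig(
    beta_colonisation=(-2.0, 1.0, 0.5, -2.5),
    beta_extinction=(-2.0, -1.0, -0.5, 2.5),
)


def event_model_table(
    study: SyntheticStudy,
    mode: str,
    surfaces: dict | None = None,
    seed: int | None = None,
    include_distances: bool = True,
    weighting: str = "uniform",
) -> pd.DataFrame:
    """Assemble one success/failure table from a synthetic study.

    Applies the comparability mask and roster filter, restricts the
    suitability surfaces (ground-truth surfaces by default) to the
    masked cells, and delegates to the event-table assembler.
    """
    masked = atlas_io.apply_study_mask(study.atlas, True)
    kept = atlas_io.filter_roster(study.atlas, study.roster)
    roster = {r.species_id: r for r in study.roster if r.species_id in kept}
    surfaces = surfaces if surfaces is not None else study.true_surfaces()
    restricted = {
        sp: s.restrict(masked.grid.index) for sp, s in surfaces.items() if sp in kept
    }
    return events.assemble_table(
        masked,
        roster,
        restricted,
        study.landcover["era1"].loc[masked.grid.index],
        study.landcover["era2"].loc[masked.grid.index],
        study.habitat_schemes,
        mode=mode,
        weighting=weighting,
        seed=seed,
        include_distances=include_distances,
    )


def fit_event_model(
    table: pd.DataFrame,
    tree: str,
    fixed_effects: list[str],
    config: glmm.MCMCConfig,
) -> glmm.PosteriorDraws:
    """Fit the binary mixed model for one tree and one absence resample."""
    species = sorted(table["species_id"].unique())
    A = glmm.phylo_correlation(tree, species)
    effects = [f for f in fixed_effects if f in table.columns]
    return glmm.fit_binary_mixed(table, A, effects, config)


def fit_species_ensembles(
    study: SyntheticStudy,
    species: list[str],
    combo: tuple[str, ...],
    blocks: list[sdm.SamplingBlock],
    config: sdm.SDMConfig,
) -> dict[str, sdm.SuitabilitySurface]:
    """Fitted 40-model ensemble suitability surfaces for a species subset."""
    bio1 = study.bioclim("era1")[list(combo)]
    bio2 = study.bioclim("era2")[list(combo)]
    out = {}
    for sp in species:
        y = study.atlas.presence_vector(sp, "era1")
        fits = sdm.fit_all_techniques(sp, combo, blocks, y, bio1, config)
        out[sp] = sdm.suitability_surface(fits, bio1, bio2)
    return out
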