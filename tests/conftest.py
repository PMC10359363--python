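import numpy as np
import pandas as pd
import pytest

from avishift import sdm
from avishift.simulate import StudyConfig, generate_study


def toy_grid(n: int, lon0: float = 10.0, lat0: float = 45.0, side_km: float = 50.0,
             comparable=None) -> pd.DataFrame:
    """Minimal valid grid table with n cells on a longitude transect."""
    comparable = [True] * n if comparable is None else comparable
    return pd.DataFrame(
        {
            "cell_id": [f"g{i}" for i in range(n)],
            "lon": lon0 + 0.5 * np.arange(n),
            "lat": np.full(n, lat0),
            "side_km": side_km,
            "country": ["X"] * n,
            "comparable": comparable,
            "ecoregion_unit": [f"E{i % 3}" for i in range(n)],
            "alt_range_m": np.linspace(100, 500, n),
            "protected_km2": np.linspace(0, 200, n),
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """16 x 16 grid, 20 species: the workhorse for module-level checks."""
    return generate_study(StudyConfig(n_lat=16, n_lon=16, n_species=20), seed=42)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (24 x 24 grid, 60 species)."""
    return generate_study(StudyConfig(), seed=7)


@pytest.fixture(scope="session")
def small_blocks(small_study):
    return sdm.build_blocks(
        small_study.grid, small_study.bioclim("era1"), k=10, seed=0
    )


@pytest.fixture(scope="session")
def ensemble_fits(small_study, small_blocks):
    """The 40 fitted models (4 techniques x 10 blocks) for one species."""
    study = small_study
    sizes = {sp: study.atlas.range_size(sp, "era1") for sp in study.atlas.species_ids}
    sp = min(sizes, key=lambda s: abs(sizes[s] - 80))  # mid-prevalence species
    combo = ("tmean_annual", "prec_annual", "temp_seasonality")
    y = study.atlas.presence_vector(sp, "era1")
    bio1 = study.bioclim("era1")
    fits = sdm.fit_all_techniques(
        sp, combo, small_blocks, y, bio1[list(combo)], sdm.SDMConfig.desk(seed=0)
    )
    return {"species": sp, "combo": combo, "fits": fits}
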