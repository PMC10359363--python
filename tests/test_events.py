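import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from avishift import atlas as al
from avishift import events as ev
from avishift.rangeshift import CentreOfGravity, great_circle_km

from conftest import toy_grid


def _atlas(patterns: dict[str, tuple[list[bool], list[bool]]]) -> al.OccupancyAtlas:
    n = len(next(iter(patterns.values()))[0])
    grid = toy_grid(n)
    cols = {}
    for sp, (p1, p2) in patterns.items():
        cols[(sp, "era1")] = p1
        cols[(sp, "era2")] = p2
    pres = pd.DataFrame(cols, index=grid["cell_id"])
    pres.columns = pd.MultiIndex.from_tuples(pres.columns, names=["species_id", "era"])
    return al.OccupancyAtlas(grid=grid, presence=pres)


def test_classification_covers_all_four_patterns():
    atlas = _atlas({"sp": ([True, True, False, False], [True, False, True, False])})
    out = ev.classify_cells(atlas, "sp").set_index("cell_id")["status"]
    assert out["g0"] == "continual"
    assert out["g1"] == "extinction"
    assert out["g2"] == "colonisation"
    assert out["g3"] == "never"


def test_statuses_partition_the_cells(small_study):
    atlas = small_study.atlas
    for sp in atlas.species_ids[:5]:
        counts = ev.classify_cells(atlas, sp)["status"].value_counts()
        assert counts.sum() == len(atlas.grid)


def test_nearest_continual_distance_matches_brute_force():
    rng = np.random.default_rng(0)
    grid = toy_grid(12)
    grid = grid.assign(lat=45 + rng.uniform(-2, 2, 12)).set_index("cell_id")
    continual = ["g0", "g5", "g9"]
    targets = ["g1", "g7", "g11"]
    d = ev.dist_nearest_continual(grid, continual, targets)
    for t in targets:
        brute = min(
            great_circle_km(
                grid.loc[t, "lon"], grid.loc[t, "lat"],
                grid.loc[c, "lon"], grid.loc[c, "lat"],
            )
            for c in continual
        )
        assert d[t] == pytest.approx(brute)


def test_adjacent_cell_distance_is_about_grid_spacing():
    # two centroids 0.45 degrees of latitude apart: ~50 km on the sphere
    grid = pd.DataFrame(
        {"lon": [10.0, 10.0], "lat": [45.0, 45.45]},
        index=pd.Index(["a", "b"], name="cell_id"),
    )
    d = ev.dist_nearest_continual(grid, ["a"], ["b"])
    assert d["b"] == pytest.approx(50.0, rel=0.01)


def test_empty_continual_set_is_undefined():
    grid = toy_grid(3).set_index("cell_id")
    with pytest.raises(ValueError):
        ev.dist_nearest_continual(grid, [], ["g0"])


def test_dist_to_cog_zero_at_cog_and_symmetric():
    grid = pd.DataFrame(
        {"lon": [10.0, 10.0, 10.0], "lat": [44.0, 45.0, 46.0]},
        index=pd.Index(["s", "m", "n"], name="cell_id"),
    )
    cog = CentreOfGravity(10.0, 45.0)
    d = ev.dist_to_cog(cog, grid, ["s", "m", "n"])
    assert d["m"] == pytest.approx(0.0, abs=1e-9)
    assert d["s"] == pytest.approx(d["n"], rel=1e-6)


class TestShannonProperties:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=9))
    def test_bounded_by_log_k_and_nonnegative(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        h = ev.shannon_diversity(p)
        assert -1e-12 <= h <= np.log(len(p)) + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.floats(0.01, 10.0), min_size=2, max_size=8))
    def test_invariant_under_permutation(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        assert ev.shannon_diversity(p) == pytest.approx(
            ev.shannon_diversity(p[::-1].copy())
        )


class TestShannon:
    def test_single_category_zero(self):
        assert ev.shannon_diversity([1.0, 0.0, 0.0]) == 0.0

    def test_uniform_maximum(self):
        assert ev.shannon_diversity([0.25] * 4) == pytest.approx(np.log(4))

    def test_direct_evaluation(self):
        assert ev.shannon_diversity([0.5, 0.25, 0.25]) == pytest.approx(1.0397, abs=1e-4)

    def test_bad_proportions(self):
        with pytest.raises(ValueError):
            ev.shannon_diversity([0.5, 0.2])


class TestFavourableCover:
    def _lc(self, frac):
        other = (1 - frac) / 2
        return pd.DataFrame(
            {"forest": [frac], "grassland": [other], "urban": [other]},
            index=pd.Index(["c0"], name="cell_id"),
        )

    def test_change_arithmetic(self):
        scheme = [{"forest": {"forest"}}]
        base, change = ev.favourable_cover(self._lc(0.4), self._lc(0.3), "forest", scheme)
        assert base["c0"] == pytest.approx(0.4)
        assert change["c0"] == pytest.approx(-0.1)

    def test_mean_across_schemes(self):
        schemes = [{"forest": {"forest"}}, {"forest": {"forest", "grassland"}}]
        base, _ = ev.favourable_cover(self._lc(0.2), self._lc(0.2), "forest", schemes)
        assert base["c0"] == pytest.approx((0.2 + 0.2 + 0.4) / 2)

    def test_unmapped_habitat_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="no land-cover classes"):
            base, change = ev.favourable_cover(
                self._lc(0.2), self._lc(0.3), "cliff", [{"forest": {"forest"}}]
            )
        assert base["c0"] == 0.0 and change["c0"] == 0.0


class TestFailureSampling:
    def _events(self):
        atlas = _atlas(
            {"sp": ([True, False, False, True, False], [True, True, False, False, False])}
        )
        return atlas, ev.classify_cells(atlas, "sp")

    def test_pool_equal_to_successes_returns_whole_pool(self):
        atlas, events = self._events()
        # colonisation pool = never-occupied {g2, g4}
        with pytest.warns(UserWarning):
            got = ev.sample_failures(events, atlas.grid, 5, "colonisation", seed=0)
        assert sorted(got) == ["g2", "g4"]

    def test_same_seed_same_sample(self):
        atlas, events = self._events()
        a = ev.sample_failures(events, atlas.grid, 1, "colonisation", seed=9)
        b = ev.sample_failures(events, atlas.grid, 1, "colonisation", seed=9)
        assert a == b

    def test_pools_are_disjoint_between_modes(self):
        atlas, events = self._events()
        col_pool = set(events.loc[events["status"] == "never", "cell_id"])
        ext_pool = set(events.loc[events["status"] == "continual", "cell_id"])
        assert not col_pool & ext_pool

    def test_inverse_distance_weights_follow_one_over_d(self):
        """Pool of two cells at ~100 and ~200 km from the continual cell:
        1/d weighting selects them in ratio 2:1."""
        grid = pd.DataFrame(
            {"lon": [10.0, 10.0, 10.0], "lat": [45.0, 45.0 + 0.9, 45.0 + 1.8]},
            index=pd.Index(["base", "near", "far"], name="cell_id"),
        )
        events = pd.DataFrame(
            {"cell_id": ["base", "near", "far"], "status": ["continual", "never", "never"]}
        )
        counts = {"near": 0, "far": 0}
        n = 10_000
        for s in range(n):
            got = ev.sample_failures(
                events, grid, 1, "colonisation", weighting="inverse_distance", seed=s
            )
            counts[got[0]] += 1
        assert counts["near"] / n == pytest.approx(2 / 3, abs=0.015)

    def test_equal_distances_reduce_to_uniform(self):
        grid = pd.DataFrame(
            {"lon": [10.0, 9.0, 11.0], "lat": [45.0, 45.0, 45.0]},
            index=pd.Index(["base", "l", "r"], name="cell_id"),
        )
        events = pd.DataFrame(
            {"cell_id": ["base", "l", "r"], "status": ["continual", "never", "never"]}
        )
        picks = [
            ev.sample_failures(events, grid, 1, "colonisation",
                               weighting="inverse_distance", seed=s)[0]
            for s in range(4000)
        ]
        frac = np.mean([p == "l" for p in picks])
        assert frac == pytest.approx(0.5, abs=0.03)


class TestAssembleTable:
    def test_rows_and_z_scaling(self, small_study):
        study = small_study
        roster = {r.species_id: r for r in study.roster}
        kept = al.filter_roster(study.atlas, study.roster)
        masked = al.apply_study_mask(study.atlas, True)
        surfaces = {
            sp: s.restrict(masked.grid.index)
            for sp, s in study.true_surfaces().items()
            if sp in kept
        }
        table = ev.assemble_table(
            masked,
            {k: v for k, v in roster.items() if k in kept},
            surfaces,
            study.landcover["era1"].loc[masked.grid.index],
            study.landcover["era2"].loc[masked.grid.index],
            study.habitat_schemes,
            mode="colonisation",
            seed=3,
        )
        assert set(table["response"]) == {0, 1}
        # matched sampling: as many failures as successes unless pools ran short
        assert (table["response"] == 1).sum() >= (table["response"] == 0).sum()
        for col in ("suit_baseline", "dist_nearest_continual_km", "body_mass_g"):
            assert abs(table[col].mean()) < 1e-8
            assert table[col].std(ddof=0) == pytest.approx(1.0, abs=1e-8)

    def test_distance_columns_can_be_dropped(self, small_study):
        study = small_study
        roster = {r.species_id: r for r in study.roster}
        kept = al.filter_roster(study.atlas, study.roster)[:5]
        surfaces = {sp: s for sp, s in study.true_surfaces().items() if sp in kept}
        table = ev.assemble_table(
            study.atlas,
            {k: v for k, v in roster.items() if k in kept},
            surfaces,
            study.landcover["era1"],
            study.landcover["era2"],
            study.habitat_schemes,
            mode="extinction",
            seed=4,
            include_distances=False,
        )
        assert "dist_nearest_continual_km" not in table.columns
        assert "dist_to_cog_km" not in table.columns
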