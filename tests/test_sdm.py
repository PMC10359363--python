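import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from avishift import sdm
from avishift.rangeshift import centre_of_gravity


class TestAUC:
    def test_perfect_separation(self):
        assert sdm.auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_scores_equal(self):
        assert sdm.auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_hand_counted_pairs(self):
        # pos {0.9, 0.8}, neg {0.85, 0.7}: 3 of 4 pairs concordant
        assert sdm.auc([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0]) == 0.75

    def test_single_class_is_undefined_not_fatal(self):
        assert np.isnan(sdm.auc([0.1, 0.9], [1, 1]))

    def test_matches_reference_and_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            n = rng.integers(6, 20)
            scores = rng.random(n)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            ours = sdm.auc(scores, labels)
            # brute force over all (pos, neg) pairs
            pos, neg = scores[labels], scores[~labels]
            wins = sum((p > n_) + 0.5 * (p == n_) for p in pos for n_ in neg)
            assert ours == pytest.approx(wins / (len(pos) * len(neg)))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(30)
        labels = rng.random(30) < 0.4
        assert sdm.auc(scores, labels) == pytest.approx(
            sdm.auc(np.exp(3 * scores), labels)
        )


class TestBlocks:
    def test_units_match_blocks_one_to_one_when_equal(self):
        grid = _unit_grid(n_units=10, cells_per_unit=3)
        bio = _unit_bioclim(grid, seed=0)
        blocks = sdm.build_blocks(grid, bio, k=10, seed=1)
        assert sorted(len(b.ecoregion_units) for b in blocks) == [1] * 10
        all_cells = sorted(c for b in blocks for c in b.cell_ids)
        assert all_cells == sorted(grid.index)

    def test_fewer_units_than_blocks_errors(self):
        grid = _unit_grid(n_units=4, cells_per_unit=2)
        with pytest.raises(ValueError, match="reduce k"):
            sdm.build_blocks(grid, _unit_bioclim(grid, seed=0), k=10)

    def test_greedy_beats_random_assignments(self):
        grid = _unit_grid(n_units=20, cells_per_unit=4)
        bio = _unit_bioclim(grid, seed=2)
        blocks = sdm.build_blocks(grid, bio, k=5, seed=3)
        greedy = sdm.block_objective(blocks, bio)
        rng = np.random.default_rng(4)
        units = grid["ecoregion_unit"].unique()
        better = 0
        for _ in range(1000):
            assign = rng.integers(0, 5, len(units))
            rand_blocks = []
            for b in range(5):
                members = [u for u, a in zip(units, assign) if a == b]
                cells = grid.index[grid["ecoregion_unit"].isin(members)].tolist()
                rand_blocks.append(sdm.SamplingBlock(b + 1, members, cells, None))
            if greedy <= sdm.block_objective(rand_blocks, bio):
                better += 1
        assert better >= 990


def _unit_grid(n_units, cells_per_unit):
    n = n_units * cells_per_unit
    return pd.DataFrame(
        {
            "lon": 10 + 0.1 * np.arange(n),
            "lat": np.full(n, 45.0),
            "ecoregion_unit": [f"u{i // cells_per_unit}" for i in range(n)],
        },
        index=pd.Index([f"c{i}" for i in range(n)], name="cell_id"),
    )


def _unit_bioclim(grid, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.standard_normal((len(grid), 3)), columns=["v1", "v2", "v3"], index=grid.index
    )


class TestEnsemble:
    def _model(self, auc_value, pred):
        return sdm.FittedSDM(
            "sp", "GLM", 1, {}, auc_value, lambda f, p=pred: np.full(len(f), p)
        )

    def test_identical_predictions_pass_through(self):
        models = [self._model(0.8, 0.37) for _ in range(40)]
        feats = pd.DataFrame({"x": np.zeros(5)})
        assert np.allclose(sdm.ensemble_suitability(models, feats), 0.37)

    def test_single_positive_weight_dominates(self):
        models = [self._model(1.0, 0.9), self._model(0.5, 0.1), self._model(0.4, 0.2)]
        feats = pd.DataFrame({"x": np.zeros(3)})
        assert np.allclose(sdm.ensemble_suitability(models, feats), 0.9)

    def test_hand_computed_weighted_mean(self):
        models = [self._model(0.9, 0.8), self._model(0.7, 0.2), self._model(0.5, 0.9)]
        feats = pd.DataFrame({"x": np.zeros(2)})
        out = sdm.ensemble_suitability(models, feats)
        assert np.allclose(out, (0.4 * 0.8 + 0.2 * 0.2) / 0.6)

    def test_all_zero_weights_fall_back_to_equal(self):
        models = [self._model(0.5, 0.2), self._model(0.4, 0.8)]
        feats = pd.DataFrame({"x": np.zeros(1)})
        with pytest.warns(UserWarning, match="equal weights"):
            out = sdm.ensemble_suitability(models, feats)
        assert np.allclose(out, 0.5)

    def test_ensemble_convexity(self):
        rng = np.random.default_rng(5)
        preds = rng.random((7, 20))
        models = [
            sdm.FittedSDM("sp", "RF", i, {}, rng.uniform(0.5, 1.0),
                          lambda f, p=preds[i]: p)
            for i in range(7)
        ]
        feats = pd.DataFrame({"x": np.zeros(20)})
        out = sdm.ensemble_suitability(models, feats)
        assert (out >= preds.min(axis=0) - 1e-12).all()
        assert (out <= preds.max(axis=0) + 1e-12).all()

    def test_surface_median_by_sorting(self):
        rng = np.random.default_rng(6)
        p1 = rng.random((5, 8))
        p2 = rng.random((5, 8))
        models = [
            sdm.FittedSDM("sp", "GLM", i, {}, 0.8,
                          lambda f, a=p1[i], b=p2[i]: a if f.attrs["era"] == 1 else b)
            for i in range(5)
        ]
        f1 = pd.DataFrame({"x": np.zeros(8)})
        f1.attrs["era"] = 1
        f2 = pd.DataFrame({"x": np.zeros(8)})
        f2.attrs["era"] = 2
        surf = sdm.suitability_surface(models, f1, f2)
        assert np.allclose(surf.suitability_era1, np.sort(p1, axis=0)[2])
        assert np.allclose(surf.change, np.median(p2, axis=0) - np.median(p1, axis=0))

    def test_identical_eras_give_zero_change(self):
        models = [self._model(0.9, 0.4)]
        feats = pd.DataFrame({"x": np.zeros(4)})
        surf = sdm.suitability_surface(models, feats, feats.copy())
        assert np.allclose(surf.change, 0.0)


class TestFitting:
    def test_forty_models_per_species(self, ensemble_fits):
        fits = ensemble_fits["fits"]
        assert len(fits) == 40
        per_tech = {t: [f for f in fits if f.technique == t] for t in sdm.TECHNIQUES}
        assert all(len(v) == 10 for v in per_tech.values())
        assert sorted(f.held_out_block for f in per_tech["GLM"]) == list(range(1, 11))

    def test_strong_niche_species_are_separable(self, small_study, small_blocks):
        """A hard threshold of one variable is learnable by every technique."""
        bio = small_study.bioclim("era1")
        combo = ("tmean_annual", "prec_annual", "temp_seasonality")
        y = (bio["tmean_annual"] > bio["tmean_annual"].median()).to_numpy()
        for tech in sdm.TECHNIQUES:
            fits = sdm.fit_sdm(
                "thresh", tech, combo, small_blocks, y, bio[list(combo)],
                sdm.SDMConfig.desk(seed=1),
            )
            med = np.nanmedian([f.auc_holdout for f in fits])
            assert med >= 0.95, tech

    def test_permuted_labels_give_null_auc(self, small_study, small_blocks):
        """Label permutation destroys the signal: held-out AUC near 0.5.

        The GLM technique stands in for the shared CV machinery."""
        study = small_study
        bio = study.bioclim("era1")
        combo = ("tmean_annual", "prec_annual", "temp_seasonality")
        sp = ensembles = study.atlas.species_ids[0]
        y = study.atlas.presence_vector(sp, "era1").copy()
        rng = np.random.default_rng(7)
        medians = []
        for _ in range(20):
            rng.shuffle(y)
            fits = sdm.fit_sdm(
                "null", "GLM", combo, small_blocks, y, bio[list(combo)],
                sdm.SDMConfig.desk(seed=2),
            )
            medians.append(np.nanmedian([f.auc_holdout for f in fits]))
        assert 0.4 <= np.median(medians) <= 0.6

    def test_warming_moves_suitability_cog_poleward(self, small_study, small_blocks):
        """With a temperature niche and uniform warming, the era-2 ensemble
        suitability surface sits poleward of the era-1 surface."""
        study = small_study
        bio1, bio2 = study.bioclim("era1"), study.bioclim("era2")
        combo = ("tmean_annual", "prec_annual")
        lons = study.grid["lon"].to_numpy()
        lats = study.grid["lat"].to_numpy()
        moved_north = 0
        candidates = [
            sp for sp in study.atlas.species_ids
            if 40 <= study.atlas.range_size(sp, "era1") <= 200
        ][:5]
        for sp in candidates:
            y = study.atlas.presence_vector(sp, "era1")
            fits = []
            for tech in ("GLM", "GAM"):
                fits += sdm.fit_sdm(sp, tech, combo, small_blocks, y,
                                    bio1[list(combo)], sdm.SDMConfig.desk(seed=3))
            surf = sdm.suitability_surface(fits, bio1[list(combo)], bio2[list(combo)])
            cog1 = centre_of_gravity(lons, lats, surf.suitability_era1)
            cog2 = centre_of_gravity(lons, lats, surf.suitability_era2)
            moved_north += cog2.lat > cog1.lat
        assert moved_north >= 4

    def test_mean_holdout_auc_high_for_strong_niches(self, small_study, small_blocks):
        """Species whose occupancy is deterministic in a sharp Gaussian niche
        are modelled with high held-out discrimination (AUC >= 0.9); species
        with Bernoulli-sampled occupancy retain label noise and sit lower but
        clearly above chance."""
        study = small_study
        bio = study.bioclim("era1")
        combo = ("tmean_annual", "prec_annual", "temp_seasonality")
        cfg = sdm.SDMConfig.desk(seed=4)
        strong = []
        truth = study.ground_truth["species"]
        for sp in list(truth)[:3]:
            y = np.asarray(truth[sp]["suitability_era1"]) > 0.5  # deterministic niche
            if y.sum() < 10 or (~y).sum() < 10:
                continue
            fits = sdm.fit_sdm(sp, "GLM", combo, small_blocks, y, bio[list(combo)], cfg)
            fits += sdm.fit_sdm(sp, "RF", combo, small_blocks, y, bio[list(combo)], cfg)
            strong.append(np.nanmean([f.auc_holdout for f in fits]))
        assert strong and np.mean(strong) >= 0.9

    def test_noisy_occupancy_ensemble_beats_chance(self, ensemble_fits):
        aucs = [f.auc_holdout for f in ensemble_fits["fits"]]
        assert np.nanmean(aucs) >= 0.6
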