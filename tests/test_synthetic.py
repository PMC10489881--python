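"""Survey generator: design geometry, generative laws, determinism."""

import numpy as np
import pandas as pd
import pytest

from trailside import synthetic as syn

from conftest import make_species


class TestDesign:
    def test_default_survey_geometry(self, full_design):
        assert full_design.n_pairs == 14
        assert full_design.n_transects == 28
        assert full_design.n_quadrats_total == 280
        for p in full_design.pairs:
            assert 1580.0 <= p.elevation_m <= 1980.0
            assert p.n_quadrats == 10
        assert full_design.quadrat_width_m == 1.0
        assert full_design.quadrat_depth_m == 0.5

    def test_minimal_design_shares_elevation(self):
        d = syn.make_design(syn.SimConfig(seed=1, n_pairs=1, n_quadrats=1))
        assert d.n_transects == 2
        assert d.n_quadrats_total == 2
        transects = list(d.transects())
        assert {t[1] for t in transects} == {0, 1}
        assert transects[0][0].elevation_m == transects[1][0].elevation_m

    def test_same_seed_same_design(self):
        a = syn.make_design(syn.SimConfig(seed=9))
        b = syn.make_design(syn.SimConfig(seed=9))
        assert a == b

    @pytest.mark.parametrize("bad", [dict(n_pairs=0), dict(n_quadrats=-1),
                                     dict(image_size=(4, 4)),
                                     dict(elevation_range=(2000.0, 1500.0))])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            syn.make_design(syn.SimConfig(seed=1, **bad))


class TestTraits:
    def test_seed_determinism(self, small_design):
        sp = make_species()
        a = syn.simulate_traits(small_design, sp, seed=7)
        b = syn.simulate_traits(small_design, sp, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_null_effect_distributions_match(self, full_design):
        # bD = 0, sigma_pair = 0, bE = 0: disturbed and undisturbed means
        # agree within Monte-Carlo error
        sp = make_species(bD=0.0, bE=0.0, sigma_pair=0.0, occupancy=1.0)
        t = syn.simulate_traits(full_design, sp, seed=3)
        on = t.loc[t.disturbed == 1, "height_cm"]
        off = t.loc[t.disturbed == 0, "height_cm"]
        se = np.sqrt(on.var() / len(on) + off.var() / len(off))
        assert abs(on.mean() - off.mean()) < 3 * se

    def test_disturbance_mean_ratio_matches_generative_law(self, full_design):
        # empirical mean ratio -> exp(-0.5) within 3 MC standard errors
        sp = make_species(bD=-0.5, bE=0.0, sigma_pair=0.0, occupancy=1.0)
        big = syn.make_design(syn.SimConfig(seed=5, n_pairs=14, n_quadrats=60))
        t = syn.simulate_traits(big, sp, seed=5)
        assert len(t) > 10_000
        on = t.loc[t.disturbed == 1, "height_cm"].to_numpy()
        off = t.loc[t.disturbed == 0, "height_cm"].to_numpy()
        ratio = on.mean() / off.mean()
        se = ratio * np.sqrt(on.var() / (on.mean() ** 2 * len(on))
                             + off.var() / (off.mean() ** 2 * len(off)))
        assert abs(ratio - np.exp(-0.5)) < 3 * se

    def test_lambda_zero_gives_zero_counts(self, small_design):
        sp = make_species(lambda_rep=0.0)
        t = syn.simulate_traits(small_design, sp, seed=2)
        assert (t[["buds", "flowers", "fruits"]].fillna(-1) == 0).all().all()

    def test_sedge_has_no_reproduction_columns(self, small_design):
        sp = make_species(lambda_rep=None)
        t = syn.simulate_traits(small_design, sp, seed=2)
        assert t["buds"].isna().all()
        assert t["flowers"].isna().all()
        assert t["fruits"].isna().all()

    def test_sizes_strictly_positive(self, small_design):
        t = syn.simulate_traits(small_design, make_species(), seed=11)
        assert (t["height_cm"] > 0).all()
        assert (t["diameter_cm"] > 0).all()

    def test_invalid_params_rejected(self, small_design):
        with pytest.raises(ValueError):
            syn.simulate_traits(small_design, make_species(nb_shape=-1), seed=1)
        with pytest.raises(ValueError):
            syn.simulate_traits(
                small_design,
                syn.SpeciesParams(
                    "x",
                    syn.TraitEffects(1, 0, 0, 0),
                    syn.TraitEffects(1, 0, 0, 0),
                    sigma_pair=-0.1,
                ),
                seed=1,
            )

    def test_csv_round_trip(self, small_design, tmp_path):
        t = syn.simulate_traits(small_design,
                                [make_species(), make_species(name="sedge",
                                                              lambda_rep=None)],
                                seed=4)
        path = tmp_path / "plants.csv"
        syn.write_plant_table(t, path)
        back = syn.read_plant_table(path)
        pd.testing.assert_frame_equal(t, back)


class TestImages:
    def test_painted_pixel_count_is_exact(self, small_design):
        cfg = syn.SimConfig(seed=6, n_pairs=4, n_quadrats=4, image_size=(32, 32))
        _, cp = syn.reference_presets()
        imgs, truth = syn.simulate_cover_images(small_design, cp, cfg, seed=6)
        for img, (_, row) in zip(imgs, truth.iterrows()):
            px = img.pixels.astype(int)
            green = (px[..., 1] > px[..., 0]) & (px[..., 1] > px[..., 2])
            assert green.sum() == row["n_green"]
            assert green.sum() == round(row["true_fraction"] * 32 * 32)

    def test_image_seed_determinism(self, small_design):
        cfg = syn.SimConfig(seed=8, n_pairs=4, n_quadrats=4, image_size=(16, 16))
        _, cp = syn.reference_presets()
        a, ta = syn.simulate_cover_images(small_design, cp, cfg, seed=8)
        b, tb = syn.simulate_cover_images(small_design, cp, cfg, seed=8)
        pd.testing.assert_frame_equal(ta, tb)
        for x, y in zip(a, b):
            assert np.array_equal(x.pixels, y.pixels)

    def test_png_round_trip(self, tmp_path):
        from trailside.cover import read_image

        rng = np.random.default_rng(0)
        img = syn.QuadratImage(
            rng.integers(0, 256, size=(16, 16, 3), dtype=np.uint8), "Q"
        )
        (path,) = syn.write_images([img], tmp_path)
        assert np.array_equal(read_image(path), img.pixels)


class TestPresets:
    def test_reference_effect_sizes(self):
        species, cp = syn.reference_presets()
        by_name = {sp.name: sp for sp in species}
        assert cp.effects.disturbance == -8.38
        assert by_name["Vaccinium ovalifolium"].diameter.disturbance == -9.18
        assert by_name["Carex spp."].height.disturbance == -19.89
        assert by_name["Carex spp."].height.interaction == pytest.approx(
            0.01, abs=0.005
        )
        assert by_name["Cassiope mertensiana"].height.disturbance == 0.66
        assert by_name["Carex spp."].lambda_rep is None

    def test_presets_round_trip_serialization(self, tmp_path):
        import yaml

        species, cp = syn.reference_presets()
        payload = {"species": [sp.to_dict() for sp in species],
                   "cover": cp.to_dict()}
        path = tmp_path / "params.yaml"
        path.write_text(yaml.safe_dump(payload))
        loaded = yaml.safe_load(path.read_text())
        back = [syn.SpeciesParams.from_dict(d) for d in loaded["species"]]
        assert back == species
        assert syn.CoverParams.from_dict(loaded["cover"]) == cp

    def test_simconfig_yaml_round_trip(self, tmp_path):
        cfg = syn.SimConfig(seed=3, n_pairs=5, image_size=(24, 24))
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert syn.SimConfig.from_yaml(tmp_path / "cfg.yaml") == cfg

    def test_simconfig_requires_seed(self):
        with pytest.raises(ValueError):
            syn.SimConfig.from_dict({"n_pairs": 3})
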