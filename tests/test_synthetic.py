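"""Synthetic generators: determinism, invariants and Monte-Carlo checks
against their own configured ground truth."""

import numpy as np
import pandas as pd
import pytest

from aposematrix import phylo, synthetic, visual
from aposematrix.types import ValidationError


class TestGenSpectra:
    def test_seed_determinism(self):
        a = synthetic.gen_spectra(1, seed=1)[0]
        b = synthetic.gen_spectra(1, seed=1)[0]
        np.testing.assert_array_equal(a.values, b.values)

    def test_invariants(self):
        curves = synthetic.gen_spectra(200, seed=7)
        assert len(curves) == 200
        for c in curves[:10]:
            assert c.values.size == 401
            assert (c.values >= 0).all()

    def test_sample_mean_matches_large_sample_mean(self):
        small = np.stack([c.values for c in synthetic.gen_spectra(200, seed=7)])
        big = np.stack([c.values for c in synthetic.gen_spectra(2000, seed=8)])
        se = big.std(0, ddof=1) / np.sqrt(200)
        assert (np.abs(small.mean(0) - big.mean(0)) < 3 * se + 3 * big.std(0) / np.sqrt(2000)).all()

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValidationError):
            synthetic.gen_spectra(0)


class TestGenSensorSets:
    def test_default_channels(self, receptors, camera):
        assert receptors.names == ("UV", "SW", "MW", "LW", "D")
        assert len(camera.names) >= 4

    def test_unit_area_normalization(self, receptors, camera):
        for bank in (receptors, camera):
            wl = bank.wavelengths
            for curve in bank.sensitivities:
                assert np.trapezoid(curve.values, wl) == pytest.approx(1.0, abs=1e-9)

    def test_narrow_width_concentrates_mass(self):
        rec, _ = synthetic.gen_sensor_sets(
            receptor_widths={c: 0.01 for c in ("UV", "SW", "MW", "LW", "D")}
        )
        wl = rec.wavelengths
        for curve in rec.sensitivities:
            total = np.trapezoid(curve.values, wl)
            peak_bin = curve.values.max() * 1.0  # 1 nm grid spacing
            assert peak_bin / total > 0.99

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_sensor_sets(receptor_peaks={"UV": 250.0})


class TestSpecimenPopulation:
    def test_paper_scale_population(self):
        pop, truth = synthetic.gen_specimen_population(16, 20, 10.0, seed=3)
        assert len(pop) == 320
        assert pop["species"].nunique() == 16
        assert set(pop["habitat_use"]) == {"generalist", "specialist"}
        assert pop["melanic"].any()
        assert pop["spot_area_fraction"].between(0, 1).all()
        assert truth.seed == 3

    def test_zero_separation_gives_identical_true_means(self):
        _, truth = synthetic.gen_specimen_population(5, 4, 0.0, seed=1)
        means = truth.extras["true_means"]
        assert np.ptp(means, axis=0).max() == 0.0

    def test_sample_means_recover_true_means(self):
        pop, truth = synthetic.gen_specimen_population(3, 50, 5.0, seed=9)
        sd = truth.extras["within_sd"]
        for i, sp in enumerate(truth.species_labels):
            sub = pop[pop["species"] == sp]
            est = np.log(sub[[f"elytra_q{c}" for c in ("UV", "SW", "MW", "LW", "D")]]).mean()
            true = truth.extras["true_means"][i][:5]
            se = sd[:5] / np.sqrt(50)
            assert (np.abs(est.to_numpy() - true) < 3.5 * se).all()

    def test_negative_separation_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_specimen_population(3, 5, -1.0)


class TestBackgroundSet:
    def test_rows_and_positivity(self):
        df = synthetic.gen_background_set("green", 10, seed=1)
        assert len(df) == 10
        assert (df[["qUV", "qSW", "qMW", "qLW", "qD"]] > 0).all().all()

    def test_determinism(self):
        a = synthetic.gen_background_set("brown", 5, seed=2)
        b = synthetic.gen_background_set("brown", 5, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_green_is_mw_dominant_relative_to_brown(self):
        g = synthetic.gen_background_set("green", 1000, seed=3)
        b = synthetic.gen_background_set("brown", 1000, seed=4)
        assert (g["qMW"] / g["qLW"]).mean() > (b["qMW"] / b["qLW"]).mean()

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.gen_background_set("urban", 5)


class TestConspicuousnessStudy:
    def test_bookkeeping_and_determinism(self):
        s1 = synthetic.gen_conspicuousness_study(8, 10, seed=5)
        s2 = synthetic.gen_conspicuousness_study(8, 10, seed=5)
        pd.testing.assert_frame_equal(s1.specimens, s2.specimens)
        assert len(s1.specimens) == 80
        assert s1.specimens["melanic"].sum() > 0
        assert s1.site_backgrounds["site"].nunique() == 8

    def test_background_sample_means_are_calibrated(self):
        study = synthetic.gen_conspicuousness_study(6, 5, seed=2)
        g = study.green_samples[["qUV", "qSW", "qMW", "qLW", "qD"]].mean().to_numpy()
        np.testing.assert_allclose(g, synthetic.BACKGROUND_TEMPLATES["green"], rtol=1e-12)

    def test_specialist_own_background_is_farther(self, noise):
        study = synthetic.gen_conspicuousness_study(16, 5, seed=7)
        spec = study.specimens
        own = study.site_backgrounds.groupby("site")[["qUV", "qSW", "qMW", "qLW"]].mean()
        g = synthetic.BACKGROUND_TEMPLATES["green"][:4]
        ratios = []
        for sp, sub in spec[~spec.melanic].groupby("species"):
            e = sub[[f"elytra_q{c}" for c in ("UV", "SW", "MW", "LW")]].mean().to_numpy()
            o = own.loc[sub["site"].iloc[0]].to_numpy()
            ratios.append(
                (sub["habitat_use"].iloc[0],
                 visual.chromatic_jnd(e, o, noise) / visual.chromatic_jnd(e, g, noise))
            )
        gen = [r for h, r in ratios if h == "generalist"]
        spc = [r for h, r in ratios if h == "specialist"]
        assert np.mean(spc) > 1.4
        assert abs(np.mean(gen) - 1.0) < 0.1


class TestRenderSpecimenImage:
    def test_identity_rendering_is_exact(self, camera, illuminant):
        el, sp = synthetic.gen_spectra(2, seed=4)
        img = synthetic.render_specimen_image(
            el, sp, [0.4], camera, illuminant, gamma=1.0, noise_sd=0.0, seed=0
        )
        region = img.image[img.masks["elytra"]]
        np.testing.assert_allclose(
            region, np.broadcast_to(img.truth_linear["elytra"], region.shape),
            atol=1e-12,
        )

    def test_one_standard_patch_per_standard(self, camera, illuminant):
        el, sp = synthetic.gen_spectra(2, seed=4)
        one = synthetic.render_specimen_image(el, sp, [0.4], camera, illuminant)
        two = synthetic.render_specimen_image(el, sp, [0.08, 0.95], camera, illuminant)
        assert [k for k in one.masks if k.startswith("standard")] == ["standard_0"]
        assert sorted(k for k in two.masks if k.startswith("standard")) == [
            "standard_0", "standard_1",
        ]

    def test_specular_pixels_are_strong_outliers(self, camera, illuminant):
        el, sp = synthetic.gen_spectra(2, seed=5, mean=-2.0)
        img = synthetic.render_specimen_image(
            el, sp, [0.4], camera, illuminant, gamma=1.0, noise_sd=0.0, seed=0,
            specular_fraction=0.01, specular_multiplier=10.0,
        )
        region = img.image[img.masks["elytra"]]
        assert (np.percentile(region, 99, axis=0) >= 5 * np.median(region, axis=0)).all()

    def test_bad_gamma_rejected(self, camera, illuminant):
        el, sp = synthetic.gen_spectra(2, seed=4)
        with pytest.raises(ValidationError):
            synthetic.render_specimen_image(el, sp, [0.4], camera, illuminant, gamma=0.0)


class TestTreeTraits:
    def test_tip_count_and_newick_round_trip(self):
        nwk, traits, _ = synthetic.gen_tree_traits(13, seed=5)
        tree = phylo.read_newick(nwk)
        assert tree.n_tips == 13
        assert set(traits.index) == set(tree.taxa)
        again = phylo.read_newick(tree.to_newick())
        assert again.taxa == tree.taxa
        np.testing.assert_allclose(again.C, tree.C, atol=1e-9)

    def test_lambda_bounds_enforced(self):
        with pytest.raises(ValidationError):
            synthetic.gen_tree_traits(8, lambda_true=1.5)

    @pytest.mark.parametrize("lam", [0.0, 1.0])
    def test_trait_covariance_matches_configured_truth(self, lam):
        nwk, traits, truth = synthetic.gen_tree_traits(
            8, lambda_true=lam, sigma2=1.0, seed=3, n_traits=1500
        )
        C_lam = phylo.lambda_cov(truth.extras["C"], lam)
        emp = np.cov(traits.to_numpy())
        # entrywise 4-SE band; SE of a covariance entry ~ sqrt((cii cjj + cij^2)/n)
        n = 1500
        cii = np.diag(C_lam)
        se = np.sqrt((np.outer(cii, cii) + C_lam**2) / n)
        assert (np.abs(emp - C_lam) < 4 * se + 1e-9).all()


class TestSimulateContrastResponse:
    def test_shape_and_null_effects(self):
        tab = synthetic.simulate_contrast_response(4, 5, seed=0)
        assert len(tab) == 4 * 5 * 3
        assert set(tab["bg_type"]) == {"brown", "green", "own"}

    def test_type_effect_applied(self):
        tab = synthetic.simulate_contrast_response(
            16, 20, type_effects={"brown": 0.5}, sigma_resid=0.01,
            sigma_indiv=0.01, sigma_species=0.01, seed=1,
        )
        diff = (
            tab[tab.bg_type == "brown"]["log_chromatic"].mean()
            - tab[tab.bg_type == "green"]["log_chromatic"].mean()
        )
        assert diff == pytest.approx(0.5, abs=0.02)
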