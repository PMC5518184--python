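"""Colour mathematics: integration, noise ratios, RNL distances,
tetrahedral geometry and hue ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aposematrix import synthetic, visual
from aposematrix.types import ConeCatch, SensorSet, SpectralCurve, ValidationError

catch_strategy = st.lists(
    st.floats(min_value=0.01, max_value=5.0), min_size=4, max_size=4
)


class TestIntegrateConeCatch:
    def test_perfect_reflector_gives_unit_catch(self, receptors, illuminant):
        wl = illuminant.wavelengths
        white = SpectralCurve(wl, np.ones_like(wl))
        for sens in receptors.sensitivities:
            assert visual.integrate_cone_catch(white, sens, illuminant) == pytest.approx(1.0)

    def test_flat_reflectance_scales_linearly(self, receptors, illuminant):
        wl = illuminant.wavelengths
        grey = SpectralCurve(wl, np.full_like(wl, 0.5))
        got = visual.integrate_cone_catch(grey, receptors.sensitivities[0], illuminant)
        assert got == pytest.approx(0.5, abs=1e-12)

    def test_matches_fine_grid_integration(self, illuminant):
        wl = np.arange(300.0, 701.0, 1.0)
        fine = np.arange(300.0, 700.05, 0.1)
        rng = np.random.default_rng(0)
        spectrum = synthetic.gen_spectra(1, seed=3)[0]
        sens_c = np.exp(-0.5 * ((wl - 500) / 30.0) ** 2)
        sens_f = np.exp(-0.5 * ((fine - 500) / 30.0) ** 2)
        refl_f = np.interp(fine, wl, spectrum.values)
        ill_f = np.interp(fine, wl, illuminant.values)
        coarse = visual.integrate_cone_catch(
            spectrum, SpectralCurve(wl, sens_c), illuminant
        )
        fine_val = np.trapezoid(refl_f * ill_f * sens_f, fine) / np.trapezoid(
            ill_f * sens_f, fine
        )
        assert coarse == pytest.approx(fine_val, abs=1e-4)

    def test_grid_mismatch_rejected(self, receptors, illuminant):
        short = SpectralCurve(np.arange(400.0, 701.0), np.ones(301))
        with pytest.raises(ValidationError):
            visual.integrate_cone_catch(short, receptors.sensitivities[0], illuminant)


class TestNoiseRatios:
    @pytest.mark.parametrize(
        "abund, expected_uv",
        [({"UV": 1.0, "SW": 1.0, "MW": 1.0, "LW": 1.0, "D": 1.0}, 0.05),
         ({"UV": 0.25, "SW": 1.0, "MW": 1.0, "LW": 1.0, "D": 1.0}, 0.10)],
    )
    def test_analytic_values(self, abund, expected_uv):
        rec, _ = synthetic.gen_sensor_sets(abundances=abund, weber=0.05)
        nv = visual.noise_ratios(rec)
        assert nv.omega[0] == pytest.approx(expected_uv)

    def test_most_abundant_cone_gets_weber_fraction_exactly(self, receptors, noise):
        assert noise.omega[np.argmax(receptors.abundances[:4])] == 0.05

    def test_requires_abundances(self, camera):
        with pytest.raises(ValidationError):
            visual.noise_ratios(camera)


class TestChromaticJnd:
    def test_identity(self, noise):
        a = ConeCatch(0.2, 0.3, 0.4, 0.5, 0.3)
        assert visual.chromatic_jnd(a, a, noise) == 0.0

    @given(q=catch_strategy, c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_uniform_scaling_cancels(self, q, c, noise):
        q = np.asarray(q)
        assert visual.chromatic_jnd(q, c * q, noise) == pytest.approx(0.0, abs=1e-9)

    def test_symmetry_on_random_pairs(self, noise):
        rng = np.random.default_rng(11)
        a = np.exp(rng.normal(size=(1000, 4)))
        b = np.exp(rng.normal(size=(1000, 4)))
        np.testing.assert_allclose(
            visual.chromatic_jnd(a, b, noise), visual.chromatic_jnd(b, a, noise),
            rtol=1e-12,
        )

    def test_specified_pair_matches_quadratic_oracle(self, rnl_oracle):
        from aposematrix.types import NoiseVector

        a = np.array([0.50, 0.40, 0.30, 0.20])
        b = np.array([0.45, 0.42, 0.28, 0.25])
        nv = NoiseVector(omega=np.array([0.10, 0.07, 0.05, 0.05]), omega_d=0.05)
        expected = rnl_oracle(a, b, nv.omega)
        assert visual.chromatic_jnd(a, b, nv) == pytest.approx(expected, rel=1e-12)

    def test_rejects_nonpositive_catches(self, noise):
        with pytest.raises(ValidationError):
            visual.chromatic_jnd(np.array([0.0, 1, 1, 1]), np.ones(4), noise)


class TestAchromaticJnd:
    def test_identity_and_analytic_value(self):
        assert visual.achromatic_jnd(0.3, 0.3, 0.05) == 0.0
        assert visual.achromatic_jnd(np.e * 0.2, 0.2, 0.05) == pytest.approx(20.0)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = np.exp(rng.normal(size=(2, 1000)))
        np.testing.assert_allclose(
            visual.achromatic_jnd(a, b, 0.05), visual.achromatic_jnd(b, a, 0.05)
        )

    def test_internal_contrast_delegates(self):
        spot = ConeCatch(0.1, 0.1, 0.1, 0.1, 0.4)
        elytra = ConeCatch(0.1, 0.1, 0.1, 0.1, 0.2)
        assert visual.internal_contrast(spot, elytra, 0.05) == pytest.approx(
            np.log(2) / 0.05
        )


class TestTetrahedralSpace:
    def test_achromatic_centre(self):
        assert visual.tetra_point([1, 1, 1, 1]).saturation == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("channel", range(4))
    def test_single_channel_vertex_saturation(self, channel):
        q = np.full(4, 1e-12)
        q[channel] = 1.0
        assert visual.tetra_point(q).saturation == pytest.approx(0.75, abs=1e-9)

    def test_vertices_equidistant(self):
        v = visual.tetra_vertices()
        dists = [np.linalg.norm(v[i] - v[j]) for i in range(4) for j in range(i + 1, 4)]
        assert np.ptp(dists) < 1e-9

    def test_channel_permutation_preserves_saturation(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            q = np.exp(rng.normal(size=4))
            s0 = visual.tetra_point(q).saturation
            for perm in ([1, 0, 2, 3], [3, 2, 1, 0], [2, 3, 0, 1]):
                assert visual.tetra_point(q[perm]).saturation == pytest.approx(s0)


class TestHueRatios:
    def test_printed_arithmetic(self):
        hp = visual.hue_ratios(np.array([1.0, 1.0, 2.0, 2.0]))
        assert (hp.h1, hp.h2) == (2.0, 1.0)
        eq = visual.hue_ratios(np.array([1.0, 1.0, 1.0, 1.0]))
        assert (eq.h1, eq.h2) == (1.0, 1.0)

    @given(q=catch_strategy, k=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_scale_invariance(self, q, k):
        q = np.asarray(q)
        a, b = visual.hue_ratios(q), visual.hue_ratios(k * q)
        assert a.h1 == pytest.approx(b.h1) and a.h2 == pytest.approx(b.h2)


class TestPcaChannelLoadings:
    def test_matches_explicit_eigendecomposition(self):
        rng = np.random.default_rng(9)
        x = np.exp(rng.normal(size=(100, 4)))
        loadings, var = visual.pca_channel_loadings(x)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        evals = np.sort(np.linalg.eigvalsh(np.cov(z, rowvar=False)))[::-1]
        np.testing.assert_allclose(var, 100 * evals / evals.sum(), rtol=1e-9)
        assert var.sum() == pytest.approx(100.0, abs=1e-9)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=200)
        x = np.stack([base, 2 * base + 1], axis=1)
        _, var = visual.pca_channel_loadings(x)
        assert var[0] == pytest.approx(100.0)

    def test_constant_column_rejected(self):
        x = np.ones((10, 3))
        with pytest.raises(ValidationError):
            visual.pca_channel_loadings(x)


class TestAttributeTable:
    def test_columns_and_consistency(self, noise):
        pop, _ = synthetic.gen_specimen_population(4, 5, 3.0, seed=0)
        at = visual.attribute_table(pop, noise)
        for col in ("elytra_h1", "elytra_h2", "elytra_saturation", "spot_luminance",
                    "spot_saturation", "spot_h1", "internal_contrast", "spot_area_pct"):
            assert col in at.columns
        assert (at["internal_contrast"] >= 0).all()
        assert at["spot_area_pct"].between(0, 100).all()
        row = pop.iloc[0]
        hp = visual.hue_ratios(
            np.array([row[f"elytra_q{c}"] for c in ("UV", "SW", "MW", "LW")])
        )
        assert at.loc[0, "elytra_h1"] == pytest.approx(hp.h1)
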