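import numpy as np
import pytest

from lepivision import (
    QuantumCatches,
    Spectrum,
    ViewingConditions,
    achromatic_distance,
    chromatic_distance,
    chromatic_distance_from_df,
    chromaticity_coords,
    make_visual_system,
    noise_vector,
    quantum_catch,
)
from lepivision.vision import (
    AdaptationError,
    TETRAHEDRON_VERTICES,
    TRIANGLE_VERTICES,
    Receptor,
    VisualSystem,
    visual_system_from_config,
)

from conftest import brute_force_chromatic


class TestPresets:
    def test_fessonia_parameters(self, fessonia):
        assert [r.lambda_max for r in fessonia.receptors] == [355.0, 431.0, 530.0]
        assert [r.density for r in fessonia.receptors] == [0.15, 0.13, 1.0]
        np.testing.assert_allclose(noise_vector(fessonia), [0.13, 0.06, 0.12])
        assert fessonia.achromatic.lambda_max == 530.0
        assert fessonia.weber_achromatic == 0.16

    def test_uv_bird_parameters(self, uv_bird):
        assert [r.lambda_max for r in uv_bird.receptors] == [372.0, 449.0, 502.0, 563.0]
        assert [r.density for r in uv_bird.receptors] == [1.0, 2.0, 2.0, 4.0]
        assert uv_bird.weber == 0.10
        assert uv_bird.achromatic.lambda_max == 563.0
        assert uv_bird.weber_achromatic == 0.18

    def test_violet_bird_parameters(self, violet_bird):
        assert [r.lambda_max for r in violet_bird.receptors] == [418.0, 453.0, 507.0, 571.0]
        assert [r.density for r in violet_bird.receptors] == [1.0, 2.0, 4.0, 4.0]
        assert violet_bird.weber == 0.06
        assert violet_bird.achromatic.lambda_max == 571.0
        assert violet_bird.weber_achromatic == 0.22

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_visual_system("pigeon")

    def test_custom_system_from_config(self):
        vs = visual_system_from_config({
            "name": "dichromat",
            "receptors": [
                {"name": "s", "lambda_max": 430, "weber": 0.1},
                {"name": "l", "lambda_max": 560, "weber": 0.1},
            ],
            "achromatic": {"lambda_max": 560},
            "weber_achromatic": 0.2,
        })
        assert vs.n_receptors == 2
        np.testing.assert_allclose(noise_vector(vs), [0.1, 0.1])


class TestNoiseVector:
    def test_density_scaling_from_reference(self, uv_bird):
        # e_i = w_ref * sqrt(eta_ref / eta_i) with w = 0.1 on the longest cone
        np.testing.assert_allclose(
            noise_vector(uv_bird),
            [0.2, 0.1 * np.sqrt(2), 0.1 * np.sqrt(2), 0.1],
        )

    def test_equal_densities_give_uniform_noise(self):
        vs = VisualSystem(
            name="flat",
            receptors=tuple(
                Receptor(n, l, density=1.0) for n, l in [("a", 400.0), ("b", 500.0)]
            ),
            noise_mode="density_scaled", weber=0.1, weber_reference="a",
        )
        np.testing.assert_allclose(noise_vector(vs), [0.1, 0.1])

    def test_missing_weber_rejected(self):
        with pytest.raises(ValueError, match="Weber"):
            VisualSystem(
                name="bad",
                receptors=(Receptor("a", 400.0, weber=0.1), Receptor("b", 500.0)),
                noise_mode="per_receptor",
            )


class TestQuantumCatch:
    def _flat(self, grid, level, label=""):
        return Spectrum(grid, np.full(grid.size, level), kind="reflectance", label=label)

    def test_zero_reflectance_errors_on_adaptation(self, grid, flat_conditions, fessonia):
        with pytest.raises(AdaptationError):
            quantum_catch(self._flat(grid, 0.0), flat_conditions, fessonia)

    def test_linearity_in_reflectance(self, grid, flat_conditions, fessonia):
        rng = np.random.default_rng(0)
        r = Spectrum(grid, 0.05 + 0.4 * rng.random(grid.size))
        q1 = quantum_catch(r, flat_conditions, fessonia)
        q2 = quantum_catch(r.with_values(2 * r.values), flat_conditions, fessonia)
        np.testing.assert_allclose(q2.Q, 2 * q1.Q, rtol=1e-12)
        assert q2.Q_achro == pytest.approx(2 * q1.Q_achro, rel=1e-12)

    def test_background_maps_to_zero_signals(self, grid, flat_conditions, fessonia):
        q = quantum_catch(flat_conditions.background, flat_conditions, fessonia)
        np.testing.assert_allclose(q.f, 0.0, atol=1e-12)
        assert q.f_achro == pytest.approx(0.0, abs=1e-12)

    def test_catches_nonnegative(self, grid, flat_conditions, uv_bird):
        q = quantum_catch(self._flat(grid, 0.5), flat_conditions, uv_bird)
        assert np.all(q.Q > 0)
        assert q.f.size == 4


class TestChromaticDistance:
    def test_identical_catches_zero(self, fessonia):
        q = QuantumCatches(Q=np.ones(3), f=np.array([0.1, 0.2, 0.3]))
        assert chromatic_distance(q, q, fessonia) == 0.0

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_uniform_offset_is_achromatic(self, n):
        e = np.full(n, 0.1)
        assert chromatic_distance_from_df(np.full(n, 0.37), e) == pytest.approx(0.0, abs=1e-9)

    def test_trichromat_hand_value(self):
        # e = (0.1, 0.1, 0.1), df = (0, 0, 0.1) -> sqrt(2/3)
        d = chromatic_distance_from_df(np.array([0.0, 0.0, 0.1]), np.full(3, 0.1))
        assert d == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_closed_form_equals_brute_force_oracle(self, n):
        """1000 random log-signal differences per receptor count: the closed
        form matches the noise-weighted line element restricted to the
        chromatic subspace to 1e-9."""
        rng = np.random.default_rng(123 + n)
        for _ in range(1000):
            df = rng.normal(0, 0.5, n)
            e = rng.uniform(0.02, 0.3, n)
            got = chromatic_distance_from_df(df, e)
            want = brute_force_chromatic(df, e)
            assert got == pytest.approx(want, abs=1e-9)

    def test_dichromat_limit_of_trichromat(self):
        """Sending one receptor's noise to infinity reduces the trichromat
        formula to the dichromat formula on the remaining pair."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            df = rng.normal(0, 0.5, 3)
            e12 = rng.uniform(0.02, 0.3, 2)
            tri = chromatic_distance_from_df(df, np.array([*e12, 1e6]))
            di = chromatic_distance_from_df(df[:2], e12)
            assert tri == pytest.approx(di, rel=1e-6)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(99)
        e = rng.uniform(0.05, 0.2, 4)
        for _ in range(200):
            fa, fb, fc = rng.normal(0, 0.5, (3, 4))
            dab = chromatic_distance_from_df(fa - fb, e)
            dba = chromatic_distance_from_df(fb - fa, e)
            assert dab == pytest.approx(dba, abs=1e-12)
            dac = chromatic_distance_from_df(fa - fc, e)
            dcb = chromatic_distance_from_df(fc - fb, e)
            assert dab <= dac + dcb + 1e-12

    def test_scaling_both_stimuli_leaves_ds_unchanged(self, grid, flat_conditions, fessonia):
        rng = np.random.default_rng(4)
        ra = Spectrum(grid, 0.05 + 0.4 * rng.random(grid.size))
        rb = Spectrum(grid, 0.05 + 0.4 * rng.random(grid.size))
        qa = quantum_catch(ra, flat_conditions, fessonia)
        qb = quantum_catch(rb, flat_conditions, fessonia)
        qa2 = quantum_catch(ra.with_values(1.7 * ra.values), flat_conditions, fessonia)
        qb2 = quantum_catch(rb.with_values(1.7 * rb.values), flat_conditions, fessonia)
        assert chromatic_distance(qa, qb, fessonia) == pytest.approx(
            chromatic_distance(qa2, qb2, fessonia), rel=1e-9
        )
        # the achromatic channel, by contrast, is unchanged too (same factor
        # cancels in the ratio) but differs from the unscaled-vs-scaled case
        assert achromatic_distance(qa, qb2, fessonia) != pytest.approx(
            achromatic_distance(qa, qb, fessonia), rel=1e-3
        )


class TestAchromaticDistance:
    def test_identical_zero(self, fessonia):
        q = QuantumCatches(Q=np.ones(3), f=np.zeros(3), Q_achro=2.0, f_achro=0.5)
        assert achromatic_distance(q, q, fessonia) == 0.0

    @pytest.mark.parametrize("weber,expected", [(0.16, 4.332169878), (0.22, 3.150669002)])
    def test_catch_ratio_two_closed_form(self, weber, expected):
        """ln(2)/w for an achromatic catch ratio of 2."""
        a = QuantumCatches(Q=np.ones(3), f=np.zeros(3), Q_achro=2.0, f_achro=np.log(2.0))
        b = QuantumCatches(Q=np.ones(3), f=np.zeros(3), Q_achro=1.0, f_achro=0.0)
        vs = VisualSystem(
            name="w", receptors=tuple(
                Receptor(n, l, weber=0.1) for n, l in
                [("u", 355.0), ("s", 431.0), ("l", 530.0)]
            ),
            achromatic=Receptor("a", 530.0), weber_achromatic=weber,
        )
        assert achromatic_distance(a, b, vs) == pytest.approx(expected, abs=1e-6)


class TestChromaticityCoords:
    def test_equal_catches_at_origin(self):
        np.testing.assert_allclose(chromaticity_coords(np.ones(3)), 0.0, atol=1e-12)
        np.testing.assert_allclose(chromaticity_coords(np.ones(4)), 0.0, atol=1e-12)

    def test_pure_catch_at_vertex(self):
        np.testing.assert_allclose(
            chromaticity_coords(np.array([1.0, 0.0, 0.0])), TRIANGLE_VERTICES[0]
        )
        np.testing.assert_allclose(
            chromaticity_coords(np.array([0.0, 0.0, 0.0, 1.0])), TETRAHEDRON_VERTICES[3]
        )

    def test_swap_symmetry(self):
        """Swapping two receptors' catches reflects the point across the
        plane swapping their vertices (checked via vertex-weight identity)."""
        rng = np.random.default_rng(10)
        q = rng.random(4)
        swapped = q.copy()
        swapped[[1, 2]] = swapped[[2, 1]]
        p = chromaticity_coords(q)
        ps = chromaticity_coords(swapped)
        rel = q / q.sum()
        expected = (
            rel[0] * TETRAHEDRON_VERTICES[0] + rel[2] * TETRAHEDRON_VERTICES[1]
            + rel[1] * TETRAHEDRON_VERTICES[2] + rel[3] * TETRAHEDRON_VERTICES[3]
        )
        np.testing.assert_allclose(ps, expected, atol=1e-12)
        assert not np.allclose(p, ps)

    def test_inside_simplex_hull(self):
        rng = np.random.default_rng(11)
        for n, verts in [(3, TRIANGLE_VERTICES), (4, TETRAHEDRON_VERTICES)]:
            for _ in range(100):
                q = rng.random(n)
                p = chromaticity_coords(q)
                # recover barycentric weights; they must be a distribution
                w, *_ = np.linalg.lstsq(
                    np.vstack([verts.T, np.ones(n)]),
                    np.concatenate([p, [1.0]]), rcond=None,
                )
                assert np.all(w > -1e-9) and np.all(w < 1 + 1e-9)
                assert w.sum() == pytest.approx(1.0)

    def test_zero_catches_rejected(self):
        with pytest.raises(ValueError):
            chromaticity_coords(np.zeros(3))
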