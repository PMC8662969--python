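"""Profile builders: nanoparticle layers, brushes, bilayers, multilayers."""

import math

import numpy as np
import pytest

import specular as s

from conftest import parratt_reflectivity


class TestNanoparticleLayers:
    def test_slice_thickness(self):
        prof = s.nanoparticle_layers(0.91, 150.0, n_slices=100)
        assert prof.slice_thickness == pytest.approx(1.5)
        assert prof.n_slices == 100

    def test_boundary_values_pure_solvent(self):
        # sphere cross-section vanishes at z = 0 and z = D
        prof = s.nanoparticle_layers(0.91, 150.0, n_slices=2000)
        assert prof.solvent_frac[0] == pytest.approx(1.0, abs=2e-3)
        assert prof.solvent_frac[-1] == pytest.approx(1.0, abs=2e-3)

    def test_quarter_height_value(self):
        # ϕ_solv(z=37.5; A=0.91, D=150) = 1 − (4·0.91/150²)(150·37.5 − 37.5²)
        z = 37.5
        expected = 1.0 - (4 * 0.91 / 150.0**2) * (150.0 * z - z * z)
        # with 2 slices the first mid-plane sits exactly at z = D/4 = 37.5
        prof2 = s.nanoparticle_layers(0.91, 150.0, n_slices=2)
        assert prof2.solvent_frac[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.3175, abs=1e-4)

    def test_profile_symmetry(self):
        # ϕ_solv(z) = ϕ_solv(D − z)
        prof = s.nanoparticle_layers(0.91, 150.0, n_slices=100)
        phi = np.array(prof.solvent_frac)
        assert phi == pytest.approx(phi[::-1], abs=1e-12)

    def test_symbolic_parameters(self):
        prof = s.nanoparticle_layers("p0", "p1", n_slices=100)
        got = s.evaluate_entry(prof.solvent_frac[49], {"p0": 0.91}, 0)
        x = (50 - 0.5) / 100
        assert got == pytest.approx(1.0 - 4 * 0.91 * (x - x * x), abs=1e-12)
        assert s.evaluate_entry(prof.slice_thickness, {"p1": 150.0}, 0) == pytest.approx(1.5)

    def test_unphysical_packing_rejected(self):
        with pytest.raises(s.ModelDefinitionError):
            s.nanoparticle_layers(1.2, 150.0)

    def test_close_packing_constant(self):
        assert round(s.CLOSE_PACKING_FRACTION, 2) == 0.91
        assert s.CLOSE_PACKING_FRACTION == pytest.approx(math.pi / (2 * math.sqrt(3)))


class TestPolydisperseNanoparticles:
    def test_degenerate_distribution_matches_monodisperse(self):
        mono = s.nanoparticle_layers(0.91, 150.0, n_slices=100)
        poly = s.nanoparticle_layers_polydisperse(0.91, 150.0, 0.0, n_slices=100)
        assert np.max(np.abs(np.array(poly.solvent_frac) - np.array(mono.solvent_frac))) < 1e-9

    def test_monte_carlo_oracle_at_midplane(self):
        A, D, sig = 0.91, 150.0, 15.0
        n_slices = 100
        poly = s.nanoparticle_layers_polydisperse(A, D, sig, n_slices=n_slices)
        extent = D + 4 * sig
        # slice whose mid-plane is closest to z = D/2
        k = int(round((D / 2) / (extent / n_slices) + 0.5)) - 1
        z = (k + 0.5) * extent / n_slices
        rng = np.random.default_rng(123)
        draws = rng.normal(D, sig, 1_000_000)
        draws = draws[(draws > D - 4 * sig) & (draws < D + 4 * sig)]
        inside = draws >= z
        phi_d = np.where(inside, (4 * A / draws**2) * (draws * z - z * z), 0.0)
        mc_mean = phi_d.mean()
        mc_se = phi_d.std(ddof=1) / np.sqrt(phi_d.size)
        got = 1.0 - poly.solvent_frac[k]
        assert abs(got - mc_mean) < 3 * mc_se

    def test_solvent_fraction_rises_beyond_minimum(self):
        poly = s.nanoparticle_layers_polydisperse(0.91, 150.0, 15.0, n_slices=400)
        phi = np.array(poly.solvent_frac)
        imin = int(np.argmin(phi))
        assert np.all(np.diff(phi[imin:]) >= -1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(s.ModelDefinitionError):
            s.nanoparticle_layers_polydisperse(0.91, 150.0, -1.0)


class TestBrushLayers:
    def test_boundary_values(self):
        prof = s.brush_layers(0.10, 480.0, 2.0, n_slices=4000)
        # z → 0: ϕ_solv → 1 − ϕ(0); z → L: ϕ_solv → 1
        assert prof.solvent_frac[0] == pytest.approx(0.90, abs=1e-4)
        assert prof.solvent_frac[-1] == pytest.approx(1.0, abs=1e-3)

    def test_midpoint_value(self):
        # ϕ(0)=0.10, L=480, n=2 at z=240: ϕ_solv = 1 − 0.10(1 − 0.25) = 0.925
        # (a single slice puts the mid-plane exactly at z = L/2)
        prof = s.brush_layers(0.10, 480.0, 2.0, n_slices=1)
        assert prof.solvent_frac[0] == pytest.approx(1 - 0.10 * (1 - 0.25), abs=1e-12)
        assert prof.solvent_frac[0] == pytest.approx(0.925, abs=1e-12)

    def test_slice_thickness_tracks_length(self):
        prof = s.brush_layers(0.10, 480.0, 2.0, n_slices=100)
        assert prof.slice_thickness == pytest.approx(4.8)

    def test_symbolic_brush(self):
        prof = s.brush_layers("phi0", "L", "n_exp", n_slices=100)
        vals = {"phi0": 0.10, "L": 480.0, "n_exp": 2.0}
        got = s.evaluate_entry(prof.solvent_frac[49], vals, 0)
        x = 49.5 / 100
        assert got == pytest.approx(1 - 0.10 * (1 - x**2), abs=1e-12)
        assert s.evaluate_entry(prof.slice_thickness, vals, 0) == pytest.approx(4.8)

    def test_invalid_inputs(self):
        with pytest.raises(s.ModelDefinitionError):
            s.brush_layers(0.0, 480.0, 2.0)
        with pytest.raises(s.ModelDefinitionError):
            s.brush_layers(0.1, -1.0, 2.0)


class TestBilayerLayers:
    def test_dry_layer_sld_from_scattering_length(self):
        # sld before water penetration: b/(A_pm·t) = 6e-4/(60·15) ≈ 6.667e-7
        spec = s.BilayerSpec(A_pm=60.0, b=(6.0e-4,) * 4, V=(300.0,) * 4, t=(15.0,) * 4)
        dry = s.bilayer_dry_sld(spec)
        assert dry[0] == pytest.approx(6.0e-4 / (60.0 * 15.0))
        assert dry[0] == pytest.approx(6.667e-7, rel=1e-3)
        # the layer entry itself carries the molecular sld b/V, which the
        # mixing rule scales by (1 − ϕ_solv) = V/(A_pm·t) back to b/(A_pm·t)
        layers, _ = s.bilayer_layers(spec)
        assert layers[0].sld_re == pytest.approx(6.0e-4 / 300.0)
        assert (1 - layers[0].solvent_frac) * layers[0].sld_re == pytest.approx(dry[0])

    def test_space_filling_molecule_no_solvent(self):
        spec = s.BilayerSpec(A_pm=60.0, b=(6e-4,) * 4, V=(60.0 * 15.0,) * 4, t=(15.0,) * 4)
        layers, _ = s.bilayer_layers(spec)
        assert layers[0].solvent_frac == pytest.approx(0.0)

    def test_small_molecule_mostly_solvent(self):
        spec = s.BilayerSpec(A_pm=60.0, b=(6e-4,) * 4, V=(1e-9,) * 4, t=(15.0,) * 4)
        layers, _ = s.bilayer_layers(spec)
        assert layers[0].solvent_frac == pytest.approx(1.0, abs=1e-9)

    def test_symbolic_area_emits_constraints(self):
        spec = s.BilayerSpec(A_pm="A_pm")
        layers, constraints = s.bilayer_layers(spec)
        assert len(layers) == 4
        assert len(constraints) == 4
        assert s.check_constraints(constraints, {"A_pm": 60.0}) is True
        assert s.check_constraints(constraints, {"A_pm": 1.0}) is False

    def test_volume_conservation_identity(self):
        # wet sld == (V·(b/V) + (A_pm·t − V)·ρ_solv)/(A_pm·t) for random specs
        rng = np.random.default_rng(11)
        for _ in range(20):
            A_pm = rng.uniform(40, 80)
            t = rng.uniform(8, 20, 4)
            V = rng.uniform(0.2, 0.95, 4) * A_pm * t
            b = rng.uniform(-5e-4, 1e-3, 4)
            rho_solv = rng.uniform(-0.56e-6, 6.36e-6)
            spec = s.BilayerSpec(A_pm=A_pm, b=tuple(b), V=tuple(V), t=tuple(t))
            layers, _ = s.bilayer_layers(spec)
            for i, layer in enumerate(layers):
                wet = s.mix_solvent(layer.sld_re, layer.solvent_frac, rho_solv)
                direct = (V[i] * (b[i] / V[i]) + (A_pm * t[i] - V[i]) * rho_solv) / (A_pm * t[i])
                assert wet == pytest.approx(direct, rel=1e-12)

    def test_unphysical_volume_rejected_numerically(self):
        with pytest.raises(s.ModelDefinitionError):
            s.BilayerSpec(A_pm=10.0, b=(6e-4,) * 4, V=(900.0,) * 4, t=(10.0,) * 4)


class TestRepeatStack:
    def unit(self):
        return [
            s.Layer(3e-6, 0, 20.0, 0.0, 0.0, "a"),
            s.Layer(5e-6, 0, 15.0, 0.0, 0.0, "b"),
        ]

    def test_identity(self):
        unit = self.unit()
        assert s.repeat_stack(unit, 1) == unit

    def test_count_and_order(self):
        out = s.repeat_stack(self.unit(), 3)
        assert len(out) == 6
        assert [l.description for l in out] == ["a", "b"] * 3

    def test_invalid_count(self):
        with pytest.raises(s.ModelDefinitionError):
            s.repeat_stack(self.unit(), 0)

    def test_uniform_repeat_equals_thick_slab(self):
        # 5 repeats of a uniform unit == one slab of the same sld
        q = np.geomspace(0.01, 0.3, 100)
        unit = [s.Layer(4e-6, 0, 12.0, 0.0, 0.0, "u")]
        rep = s.repeat_stack(unit, 5)
        layers = [s.Layer(0.0, 0, 0, 0, 0, "front"), *rep, s.Layer(2.07e-6, 0, 0, 0, 0, "back")]
        model = s.SystemModel(patches=(s.Patch(layers=layers),))
        R_rep = s.reflectivity(model, {}, q)
        R_one = s.abeles_reflectivity([0.0, 4e-6, 2.07e-6], [0, 60.0, 0], [0, 0, 0], q)
        assert np.max(np.abs(R_rep - R_one) / np.maximum(R_one, 1e-300)) < 1e-12


class TestDiscretizationConvergence:
    def test_nanoparticle_slicing_converges(self):
        # refining 100 → 400 slices changes R by < 0.5% over a typical
        # solid/liquid NR fitted range (Q ≤ 0.15 Å⁻¹)
        q = np.geomspace(0.008, 0.15, 80)
        curves = {}
        for n in (100, 400):
            prof = s.nanoparticle_layers(0.91, 150.0, n_slices=n)
            layers = [
                s.Layer(2.07e-6, 0, 0, 3.0, 0.0, "Si"),
                *prof.to_layers(1.41e-6),
                s.Layer(6.36e-6, 0, 0, 0.0, 0.0, "D2O"),
            ]
            model = s.SystemModel(patches=(s.Patch(layers=layers),))
            curves[n] = s.reflectivity(model, {}, q)
        rel = np.abs(curves[400] - curves[100]) / np.maximum(curves[400], 1e-300)
        assert np.max(rel) < 0.005
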