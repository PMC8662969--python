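"""Model schema: symbolic entries, resolution, constraints."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import specular as s
from specular.model import CompiledSystem


class TestEvaluateEntry:
    def test_numeric_passthrough(self):
        assert s.evaluate_entry(3.0, {}, 0) == 3.0
        assert s.evaluate_entry(3, {"p0": 1.0}, 7) == 3.0

    def test_nanoparticle_profile_expression(self):
        # solvent fraction of a close-packed sphere layer, evaluated at the
        # mid-plane of slice 50 of 100 for D = 150 Å: z = (50 - 0.5)*1.5
        entry = "1 - (4*p0/p1**2)*(p1*((n - 0.5)*1.5) - ((n - 0.5)*1.5)**2)"
        z = (50 - 0.5) * 1.5
        expected = 1.0 - (4 * 0.91 / 150.0**2) * (150.0 * z - z * z)
        got = s.evaluate_entry(entry, {"p0": 0.91, "p1": 150.0}, 50)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.09009, abs=1e-4)

    def test_undeclared_symbol_named_in_error(self):
        with pytest.raises(s.ModelDefinitionError, match="p1"):
            s.evaluate_entry("p0 + p1", {"p0": 1.0}, 0)

    def test_layer_index_symbol(self):
        assert s.evaluate_entry("n*2", {}, 3) == 6.0

    def test_non_finite_result(self):
        with pytest.raises(s.EvaluationError):
            s.evaluate_entry("1/p0", {"p0": 0.0}, 0)

    def test_mathematical_functions_allowed(self):
        assert s.evaluate_entry("exp(0) + sqrt(4)", {}, 0) == pytest.approx(3.0)
        assert s.evaluate_entry("erf(0)", {}, 0) == 0.0


class TestParameterDeclarations:
    def test_uniform_bounds_ordered(self):
        with pytest.raises(s.ModelDefinitionError):
            s.Parameter("a", "uniform", 2.0, 1.0)

    def test_normal_sd_nonnegative(self):
        with pytest.raises(s.ModelDefinitionError):
            s.Parameter("a", "normal", 0.0, -1.0)

    def test_fixed_detection(self):
        assert s.Parameter("a", "uniform", 1.0, 1.0).is_fixed
        assert s.Parameter("a", "normal", 3.0, 0.0).is_fixed
        assert not s.Parameter("a", "uniform", 1.0, 2.0).is_fixed
        assert not s.Parameter("a", "normal", 3.0, 0.5).is_fixed

    def test_multi_parameter_validates_each_triple(self):
        with pytest.raises(s.ModelDefinitionError):
            s.MultiParameter("m", [("uniform", 0.0, 1.0), ("uniform", 2.0, 1.0)])

    def test_reserved_name_rejected(self):
        with pytest.raises(s.ModelDefinitionError):
            s.Parameter("n", "uniform", 0.0, 1.0)


def two_layer_xrr_model():
    """Air / Fe 40 Å / Au 60 Å / Si, all roughnesses 3 Å (X-ray slds)."""
    layers = [
        s.Layer(0.0, 0.0, 0.0, 3.0, 0.0, "air"),
        s.Layer(5.95e-5, 0.0, 40.0, 3.0, 0.0, "Fe"),
        s.Layer(1.247e-4, 0.0, 60.0, 3.0, 0.0, "Au"),
        s.Layer(2.0e-5, 0.0, 0.0, 0.0, 0.0, "Si"),
    ]
    return s.SystemModel(patches=(s.Patch(layers=layers, coverage=1.0),))


class TestResolveSystem:
    def test_pure_numeric_model_identity(self):
        model = two_layer_xrr_model()
        (patch,) = s.resolve_system(model, {})
        assert patch.thickness == [0.0, 40.0, 60.0, 0.0]
        assert patch.roughness == [3.0, 3.0, 3.0, 0.0]
        assert patch.sld_re[1] == 5.95e-5

    def test_numeric_model_ignores_parameter_map(self):
        model = two_layer_xrr_model()
        a = s.resolve_system(model, {})
        b = s.resolve_system(model, {"unused": 42.0})
        assert a[0].sld_re == b[0].sld_re
        assert a[0].thickness == b[0].thickness

    def test_purity(self, single_film_model):
        a = s.resolve_system(single_film_model, {"t_film": 55.0})
        b = s.resolve_system(single_film_model, {"t_film": 55.0})
        assert a[0].thickness == b[0].thickness

    def test_two_patch_coverages(self):
        base = [s.Layer(0.0, 0, 0, 0, 0, "front"), s.Layer(2e-6, 0, 0, 0, 0, "back")]
        model = s.SystemModel(
            patches=(
                s.Patch(layers=base, coverage=0.7),
                s.Patch(layers=base, coverage=0.3),
            )
        )
        patches = s.resolve_system(model, {})
        assert [p.coverage for p in patches] == [0.7, 0.3]

    def test_coverage_sum_enforced(self):
        base = [s.Layer(0.0, 0, 0, 0, 0, ""), s.Layer(2e-6, 0, 0, 0, 0, "")]
        with pytest.raises(s.ModelDefinitionError, match="coverages"):
            s.SystemModel(patches=(s.Patch(layers=base, coverage=0.5),))

    def test_minimal_two_layer_patch(self):
        model = s.SystemModel(
            patches=(
                s.Patch(
                    layers=[s.Layer(0.0, 0, 0, 0, 0, ""), s.Layer(2e-6, 0, 0, 0, 0, "")],
                    coverage=1.0,
                ),
            )
        )
        (patch,) = s.resolve_system(model, {})
        assert len(patch.sld_re) == 2

    def test_negative_thickness_rejected(self):
        model = s.SystemModel(
            patches=(
                s.Patch(
                    layers=[
                        s.Layer(0.0, 0, 0, 0, 0, ""),
                        s.Layer(2e-6, 0, "t", 0, 0, ""),
                        s.Layer(4e-6, 0, 0, 0, 0, ""),
                    ]
                ),
            )
        )
        with pytest.raises(s.ModelDefinitionError, match="thickness"):
            s.resolve_system(model, {"t": -5.0})

    def test_multi_parameter_selects_curve_triple(self):
        model = s.SystemModel(
            patches=(
                s.Patch(
                    layers=[
                        s.Layer(0.0, 0, 0, 0, 0, ""),
                        s.Layer("rho", 0, 10.0, 0, 0, ""),
                        s.Layer(4e-6, 0, 0, 0, 0, ""),
                    ]
                ),
            )
        )
        values = {"rho": [1e-6, 2e-6, 3e-6]}
        for i, expect in enumerate(values["rho"]):
            (patch,) = s.resolve_system(model, values, curve_index=i)
            assert patch.sld_re[1] == expect

    def test_multi_parameter_permutation_consistency(self):
        model = s.SystemModel(
            patches=(
                s.Patch(
                    layers=[
                        s.Layer(0.0, 0, 0, 0, 0, ""),
                        s.Layer("rho", 0, 10.0, 0, 0, ""),
                        s.Layer(4e-6, 0, 0, 0, 0, ""),
                    ]
                ),
            )
        )
        slds = [1e-6, 2e-6, 3e-6]
        perm = [2, 0, 1]
        permuted = [slds[i] for i in perm]
        for new_idx, old_idx in enumerate(perm):
            (a,) = s.resolve_system(model, {"rho": slds}, curve_index=old_idx)
            (b,) = s.resolve_system(model, {"rho": permuted}, curve_index=new_idx)
            assert a.sld_re[1] == b.sld_re[1]

    def test_compiled_system_matches_resolve(self, single_film_model):
        compiled = CompiledSystem(single_film_model)
        a = compiled.resolve({"t_film": 42.0})
        b = s.resolve_system(single_film_model, {"t_film": 42.0})
        assert a[0].thickness == b[0].thickness
        assert a[0].solvent_frac == b[0].solvent_frac

    @hsettings(deadline=None, max_examples=25)
    @given(t=st.floats(min_value=0.0, max_value=500.0))
    def test_resolution_is_pure_over_values(self, t):
        layers = [
            s.Layer(2.07e-6, 0.0, 0.0, 3.0, 0.0, "Si"),
            s.Layer(4.0e-6, 0.0, "t_film", 3.0, 0.2, "film"),
            s.Layer(6.36e-6, 0.0, 0.0, 0.0, 0.0, "D2O"),
        ]
        model = s.SystemModel(patches=(s.Patch(layers=layers),))
        a = s.resolve_system(model, {"t_film": t})
        b = s.resolve_system(model, {"t_film": t})
        assert a[0].thickness == b[0].thickness


class TestConstraints:
    def test_solvent_positivity_holds(self):
        c = [s.Constraint("1 - V/(A*t) > 0")]
        assert s.check_constraints(c, {"V": 300.0, "A": 60.0, "t": 10.0}) is True

    def test_solvent_positivity_violated(self):
        c = [s.Constraint("1 - V/(A*t) > 0")]
        assert s.check_constraints(c, {"V": 700.0, "A": 60.0, "t": 10.0}) is False

    def test_empty_list_true(self):
        assert s.check_constraints([], {}) is True

    def test_missing_name_errors(self):
        with pytest.raises(s.ModelDefinitionError, match="V"):
            s.check_constraints([s.Constraint("V > 0")], {})

    def test_non_inequality_rejected(self):
        with pytest.raises(s.ModelDefinitionError):
            s.check_constraints([s.Constraint("V + 1")], {"V": 1.0})


class TestParameterSet:
    def test_free_entry_labels_and_bounds(self):
        ps = s.ParameterSet(
            parameters=[
                s.Parameter("a", "uniform", 0.0, 1.0),
                s.Parameter("b", "uniform", 2.0, 2.0),  # fixed
                s.Parameter("c", "normal", 10.0, 2.0),
            ],
            multi_parameters=[
                s.MultiParameter(
                    "m", [("uniform", 0.0, 1.0), ("uniform", 5.0, 5.0), ("uniform", 0.0, 2.0)]
                )
            ],
        )
        labels = [e[0] for e in ps.free_entries()]
        assert labels == ["a", "c", "m[0]", "m[2]"]
        assert ps.n_free == 4
        bounds = ps.search_bounds()
        assert bounds[1] == (0.0, 20.0)  # mean ± 5 sd

    def test_vector_round_trip(self):
        ps = s.ParameterSet(
            parameters=[s.Parameter("a", "uniform", 0.0, 1.0)],
            multi_parameters=[
                s.MultiParameter("m", [("uniform", 0.0, 1.0), ("fixed", 7.0, 7.0)])
            ],
        )
        values = ps.values_from_vector([0.5, 0.25])
        assert values["a"] == 0.5
        assert values["m"] == [0.25, 7.0]

    def test_normal_penalty(self):
        ps = s.ParameterSet(parameters=[s.Parameter("c", "normal", 10.0, 2.0)])
        assert ps.normal_penalty([12.0]) == pytest.approx(1.0)
        assert ps.normal_penalty([10.0]) == 0.0
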