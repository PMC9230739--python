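import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemocal import (PreprocessSpec, SpectrumSet, WavenumberGrid,
                      apply_pipeline, area_normalize, sg_derivative, snv)
from chemocal.errors import (DegenerateSpectrumError, GridSpacingError,
                             ParameterError)

finite_vectors = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False),
    min_size=3, max_size=20,
)


class TestSNV:
    def test_closed_form(self):
        np.testing.assert_allclose(snv([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_postconditions(self):
        out = snv(np.array([0.3, 1.2, -0.7, 2.5, 0.0]))
        assert abs(out.mean()) < 1e-12
        assert abs(out.std(ddof=1) - 1.0) < 1e-12

    def test_idempotent(self):
        x = np.array([0.5, 1.5, -2.0, 4.0])
        np.testing.assert_allclose(snv(snv(x)), snv(x), atol=1e-12)

    def test_constant_vector_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            snv([5.0, 5.0, 5.0])

    @settings(deadline=None, derandomize=True)
    @given(x=finite_vectors,
           a=st.floats(min_value=0.01, max_value=50).filter(lambda v: v != 0),
           b=st.floats(min_value=-10, max_value=10),
           negate=st.booleans())
    def test_affine_invariance(self, x, a, b, negate):
        """snv(a x + b) = sign(a) snv(x) for any affine rescaling."""
        x = np.asarray(x)
        if x.std(ddof=1) < 1e-6:
            return
        a = -a if negate else a
        np.testing.assert_allclose(snv(a * x + b), np.sign(a) * snv(x),
                                   atol=1e-7)


class TestAreaNormalize:
    def test_positive_vector(self):
        np.testing.assert_allclose(area_normalize([1.0, 1.0, 2.0]),
                                   [0.25, 0.25, 0.5])

    def test_absolute_value_denominator(self):
        np.testing.assert_allclose(area_normalize([-1.0, 1.0, 2.0]),
                                   [-0.25, 0.25, 0.5])

    def test_unit_absolute_area(self):
        out = area_normalize(np.array([0.2, -1.4, 3.3, 0.0]))
        assert abs(np.abs(out).sum() - 1.0) < 1e-12

    def test_zero_vector_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            area_normalize([0.0, 0.0, 0.0])


class TestSGDerivative:
    @pytest.fixture
    def unit_grid(self):
        return WavenumberGrid(np.arange(400.0, 421.0))

    def test_exact_on_quadratic_first_derivative(self, unit_grid):
        w = unit_grid.values
        d1 = sg_derivative(w ** 2, unit_grid, 1, 2, 5)
        np.testing.assert_allclose(d1, 2 * w, rtol=1e-9)

    def test_exact_on_quadratic_second_derivative(self, unit_grid):
        w = unit_grid.values
        d2 = sg_derivative(w ** 2, unit_grid, 2, 2, 5)
        np.testing.assert_allclose(d2, 2.0, rtol=1e-9)

    def test_linear_spectrum_second_derivative_zero(self, unit_grid):
        d2 = sg_derivative(3.0 * unit_grid.values + 7, unit_grid, 2, 2, 5)
        np.testing.assert_allclose(d2, 0.0, atol=1e-9)

    @pytest.mark.parametrize("poly,deriv", [(2, 1), (3, 1), (3, 2), (4, 2)])
    def test_exact_on_polynomials_up_to_order(self, poly, deriv):
        """SG filters reproduce the derivative of any polynomial of degree
        <= polynomial order exactly, edges included."""
        grid = WavenumberGrid(np.arange(1000.0, 1000.0 + 2 * 31, 2.0))
        w = grid.values - 1030.0
        coeffs = np.array([0.3, -0.2, 0.05, 0.01, -0.002])[: poly + 1]
        x = sum(c * w ** i for i, c in enumerate(coeffs))
        expected = sum(
            c * math.factorial(i) / math.factorial(i - deriv)
            * w ** (i - deriv)
            for i, c in enumerate(coeffs) if i >= deriv
        )
        out = sg_derivative(x, grid, deriv, poly, 11)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_grid_spacing_scales_result(self):
        fine = WavenumberGrid(np.arange(400.0, 440.0, 1.0))
        coarse = WavenumberGrid(np.arange(400.0, 480.0, 2.0))
        d_fine = sg_derivative(fine.values ** 2, fine, 1, 2, 7)
        d_coarse = sg_derivative(coarse.values ** 2, coarse, 1, 2, 7)
        np.testing.assert_allclose(d_fine, 2 * fine.values, rtol=1e-9)
        np.testing.assert_allclose(d_coarse, 2 * coarse.values, rtol=1e-9)

    def test_disjoint_interval_grid_per_block(self):
        values = np.concatenate([np.arange(500.0, 541.0, 2.0),
                                 np.arange(2500.0, 2541.0, 2.0)])
        grid = WavenumberGrid(values)
        d1 = sg_derivative(values ** 2, grid, 1, 2, 5)
        np.testing.assert_allclose(d1, 2 * values, rtol=1e-9)

    def test_uneven_grid_rejected(self):
        grid = WavenumberGrid(np.array([400.0, 401.0, 403.0, 406.0, 410.0,
                                        415.0, 421.0]))
        with pytest.raises(GridSpacingError):
            sg_derivative(np.ones(7), grid, 1, 2, 5)

    def test_window_larger_than_spectrum(self, unit_grid):
        with pytest.raises(ParameterError):
            sg_derivative(np.ones(len(unit_grid)), unit_grid, 1, 2, 31)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_linearity(self, seed):
        """D(ax + by) = a D(x) + b D(y)."""
        rng = np.random.default_rng(seed)
        grid = WavenumberGrid(np.arange(400.0, 430.0, 1.0))
        x, y = rng.normal(size=(2, 30))
        a, b = rng.normal(size=2)
        lhs = sg_derivative(a * x + b * y, grid, 1, 2, 7)
        rhs = (a * sg_derivative(x, grid, 1, 2, 7)
               + b * sg_derivative(y, grid, 1, 2, 7))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)


class TestPipeline:
    def test_empty_spec_is_identity(self, tiny_set):
        out = apply_pipeline(tiny_set, PreprocessSpec(()))
        np.testing.assert_array_equal(out.matrix, tiny_set.matrix)

    def test_area_then_snv_hand_composition(self):
        grid = WavenumberGrid(np.array([500.0, 600.0, 700.0]))
        sset = SpectrumSet(grid=grid, matrix=np.array([[1.0, 1.0, 2.0]]),
                           sample_ids=["s"])
        out = apply_pipeline(sset, PreprocessSpec.parse("area_norm+snv"))
        expected = np.array([-1, -1, 2]) / np.sqrt(3)  # snv([.25,.25,.5])
        np.testing.assert_allclose(out.matrix[0], expected, rtol=1e-12)

    def test_snv_then_derivative_affine_oracle(self):
        """SNV is affine, so d/dw of snv(w^2) is 2w / sd(w^2)."""
        grid = WavenumberGrid(np.arange(400.0, 405.0))
        w = grid.values
        x = (w - 400.0) ** 2
        sset = SpectrumSet(grid=grid, matrix=x[None, :], sample_ids=["q"])
        out = apply_pipeline(
            sset, PreprocessSpec.parse("snv+d1(poly=2,window=5)"))
        expected = 2 * (w - 400.0) / x.std(ddof=1)
        np.testing.assert_allclose(out.matrix[0], expected, rtol=1e-9,
                                   atol=1e-12)

    def test_reference_and_order_untouched(self, tiny_set):
        out = apply_pipeline(tiny_set, PreprocessSpec.parse("area_norm+snv"))
        assert out.sample_ids == tiny_set.sample_ids
        np.testing.assert_array_equal(out.reference, tiny_set.reference)

    def test_failing_sample_identified(self, tiny_set):
        bad = SpectrumSet(grid=tiny_set.grid,
                          matrix=np.vstack([tiny_set.matrix,
                                            np.full(5, 0.7)]),
                          sample_ids=["s1", "s2", "s3", "flat"])
        with pytest.raises(DegenerateSpectrumError, match="flat"):
            apply_pipeline(bad, PreprocessSpec.parse("snv"))


class TestPreprocessSpec:
    @pytest.mark.parametrize("text", [
        "original", "snv", "area_norm", "area_norm+snv",
        "snv+d1(poly=2,window=11)", "d2(poly=3,window=21)",
        "d1(poly=2,window=11)+snv",
    ])
    def test_string_round_trip(self, text):
        spec = PreprocessSpec.parse(text)
        assert PreprocessSpec.parse(str(spec)) == spec

    def test_invalid_step_rejected(self):
        with pytest.raises(ParameterError):
            PreprocessSpec.parse("msc")

    def test_window_constraints_enforced(self):
        with pytest.raises(ParameterError):
            PreprocessSpec.parse("d1(poly=2,window=10)")  # even window
        with pytest.raises(ParameterError):
            PreprocessSpec.parse("d2(poly=1,window=11)")  # deriv > poly
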