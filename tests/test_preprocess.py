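"""Pretreatment contracts: trimming, replicate choice, SNV, MSC, S-G."""

import numpy as np
import pytest

from graperipe import preprocess
from graperipe.containers import ReplicateSet, SpectraMatrix
from graperipe.preprocess import (
    DegenerateSampleError,
    MscFit,
    PreprocessConfig,
    msc_fit_apply,
    representative_spectrum,
    savgol,
    snv,
    trim_bands,
)


def _spectra(values, wavelengths=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if wavelengths is None:
        wavelengths = np.arange(values.shape[1], dtype=float) + 400
    return SpectraMatrix(values, wavelengths)


class TestTrim:
    def test_boundary_inclusion(self):
        s = _spectra(np.arange(5)[None, :], [390, 400, 700, 1029, 1030])
        out = trim_bands(s, PreprocessConfig())
        assert out.wavelengths.tolist() == [400, 700, 1029]
        assert out.values.tolist() == [[1, 2, 3]]

    def test_identity_when_within_range(self):
        s = _spectra(np.random.default_rng(0).random((3, 10)))
        out = trim_bands(s, PreprocessConfig())
        np.testing.assert_array_equal(out.values, s.values)

    def test_count_on_full_instrument_grid(self):
        # the instrument grid extends 200-1100 nm at the 1507-channel step
        step = (1029 - 400) / 1506
        wl = np.arange(200.0, 1100.0 + 1e-9, step)
        s = _spectra(np.zeros((1, wl.size)), wl)
        out = trim_bands(s, PreprocessConfig())
        expected = int(((wl >= 400) & (wl <= 1029)).sum())
        assert out.n_channels == expected

    def test_empty_result_rejected(self):
        s = _spectra([[1.0, 2.0]], [100.0, 200.0])
        with pytest.raises(ValueError):
            trim_bands(s, PreprocessConfig())


class TestRepresentative:
    def test_single_replicate_returned(self):
        reps = ReplicateSet(np.arange(4.0).reshape(2, 1, 2), [400.0, 500.0])
        out, chosen = representative_spectrum(reps)
        np.testing.assert_array_equal(out.values, reps.values[:, 0])
        assert chosen.tolist() == [0, 0]

    def test_tie_breaks_to_lowest_index(self):
        vals = np.array([[[0.0, 0.0], [0.0, 0.0], [10.0, 10.0]]])
        out, chosen = representative_spectrum(ReplicateSet(vals, [400.0, 500.0]))
        assert chosen[0] == 0
        np.testing.assert_array_equal(out.values[0], [0.0, 0.0])

    def test_agrees_with_bruteforce_oracle(self, rng):
        vals = rng.normal(size=(6, 10, 15))
        reps = ReplicateSet(vals, np.arange(15.0) + 400)
        _, chosen = representative_spectrum(reps)
        for i in range(6):
            sums = [
                sum(
                    np.linalg.norm(vals[i, a] - vals[i, b])
                    for b in range(10)
                    if b != a
                )
                for a in range(10)
            ]
            assert chosen[i] == int(np.argmin(sums))


class TestSnv:
    def test_simple_row(self):
        out = snv(_spectra([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out.values, [[-1.0, 0.0, 1.0]])

    def test_rows_normalized(self, rng):
        out = snv(_spectra(rng.random((8, 30))))
        np.testing.assert_allclose(out.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(out.values.std(axis=1, ddof=1), 1, atol=1e-12)

    def test_affine_invariance(self, rng):
        x = rng.random((4, 25))
        a = snv(_spectra(x))
        b = snv(_spectra(5.0 * x + 7.0))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_constant_row_names_sample(self):
        s = SpectraMatrix(np.ones((1, 5)), np.arange(5.0) + 400, ["GRAPE42"])
        with pytest.raises(DegenerateSampleError, match="GRAPE42"):
            snv(s)


class TestMsc:
    def test_identical_rows_are_fixed_points(self):
        x = np.tile(np.linspace(0.2, 0.8, 40), (5, 1))
        out, fit = msc_fit_apply(_spectra(x))
        np.testing.assert_allclose(out.values, x, atol=1e-12)
        np.testing.assert_allclose(fit.slope_per_sample, 1.0)
        np.testing.assert_allclose(fit.offset_per_sample, 0.0, atol=1e-12)

    def test_exactly_inverts_affine_scatter(self, rng):
        ref = np.sin(np.linspace(0, 3, 60)) + 2.0
        a = rng.uniform(0.7, 1.3, size=6)
        b = rng.uniform(-0.2, 0.2, size=6)
        x = a[:, None] * ref + b[:, None]
        out, fit = msc_fit_apply(_spectra(x), reference=ref)
        np.testing.assert_allclose(out.values, np.tile(ref, (6, 1)), atol=1e-10)
        np.testing.assert_allclose(fit.slope_per_sample, a, atol=1e-10)

    def test_refit_oracle_slope_one_intercept_zero(self, rng):
        x = rng.random((7, 50)) + np.linspace(0, 1, 50)
        out, fit = msc_fit_apply(_spectra(x))
        ref = fit.reference
        design = np.column_stack([ref, np.ones_like(ref)])
        for row in out.values:
            slope, intercept = np.linalg.lstsq(design, row, rcond=None)[0]
            assert slope == pytest.approx(1.0, abs=1e-8)
            assert intercept == pytest.approx(0.0, abs=1e-8)

    def test_idempotent(self, rng):
        x = rng.random((5, 40)) + np.linspace(0.5, 1.5, 40)
        once, fit = msc_fit_apply(_spectra(x))
        twice, _ = msc_fit_apply(once, reference=fit.reference)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-10)

    def test_frozen_reference_applies_to_new_spectra(self, rng):
        cal = rng.random((10, 30)) + np.linspace(0.5, 1.0, 30)
        _, fit = msc_fit_apply(_spectra(cal))
        new = 1.4 * fit.reference + 0.3
        corrected = fit.apply(_spectra(new[None, :]))
        np.testing.assert_allclose(corrected.values[0], fit.reference, atol=1e-10)


class TestSavgol:
    def test_reproduces_degree5_polynomial_interior(self):
        t = np.linspace(-1, 1, 200)
        row = 1 + t - 0.5 * t**2 + 0.2 * t**3 - t**4 + 0.3 * t**5
        out = savgol(_spectra(row[None, :]), PreprocessConfig())
        interior = slice(11, -11)
        np.testing.assert_allclose(out.values[0][interior], row[interior], atol=1e-9)

    def test_constant_row_unchanged_everywhere(self):
        out = savgol(_spectra(np.full((1, 100), 3.7)), PreprocessConfig())
        np.testing.assert_allclose(out.values, 3.7, atol=1e-12)

    def test_coefficients_sum_to_one(self):
        """(23, 5) filter weights from a least-squares design-matrix oracle."""
        half = 11
        t = np.arange(-half, half + 1, dtype=float)
        design = np.vander(t, 6, increasing=True)  # columns 1, t, ..., t^5
        # smoothing weights = first row of (D'D)^-1 D' evaluated at t=0
        coeffs = np.linalg.pinv(design)[0]
        assert coeffs.sum() == pytest.approx(1.0, abs=1e-12)
        # and the filter reproduces them: apply to unit impulses
        from scipy.signal import savgol_coeffs

        np.testing.assert_allclose(savgol_coeffs(23, 5), coeffs[::-1], atol=1e-10)

    def test_window_larger_than_grid_rejected(self):
        with pytest.raises(ValueError):
            savgol(_spectra(np.zeros((1, 10))), PreprocessConfig())


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        scale=st.floats(0.1, 50.0, allow_nan=False),
        shift=st.floats(-100.0, 100.0, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_snv_affine_invariance_property(scale, shift, seed):
        """SNV output is invariant under any positive affine map of a row."""
        x = np.random.default_rng(seed).random((3, 20)) + 0.1
        a = snv(_spectra(x))
        b = snv(_spectra(scale * x + shift))
        np.testing.assert_allclose(a.values, b.values, atol=1e-7)

except ImportError:  # pragma: no cover - hypothesis is an optional extra
    pass


def test_sample_permutation_equivariance(rng):
    """All pretreatments are row-local: permuting samples permutes outputs."""
    x = rng.random((9, 60)) + np.linspace(0.2, 1.0, 60)
    s = _spectra(x)
    perm = rng.permutation(9)
    sp = _spectra(x[perm])
    cfg = PreprocessConfig()
    np.testing.assert_allclose(snv(sp).values, snv(s).values[perm])
    np.testing.assert_allclose(savgol(sp, cfg).values, savgol(s, cfg).values[perm])
    ref = x.mean(axis=0)
    a, _ = msc_fit_apply(sp, reference=ref)
    b, _ = msc_fit_apply(s, reference=ref)
    np.testing.assert_allclose(a.values, b.values[perm])


def test_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(sg_window=22)
    with pytest.raises(ValueError):
        PreprocessConfig(sg_window=5, sg_polyorder=5)
    with pytest.raises(ValueError):
        PreprocessConfig(method="detrend")
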