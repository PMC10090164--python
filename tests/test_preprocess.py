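"""SNV, Savitzky-Golay derivative, trimming, profiles, masks, recipes."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.signal import savgol_coeffs

from collagenmap.io import SpectralCube
from collagenmap.preprocess import (
    DegenerateSpectrumError,
    NonUniformGridError,
    PixelMask,
    PreprocessRecipe,
    apply_recipe,
    apply_recipe_matrix,
    build_background_mask,
    build_concretion_mask,
    extract_profile,
    savgol_derivative,
    snv,
    trim_wavelengths,
)
from collagenmap.synthetic import SyntheticConfig, simulate_cube


# ---------------------------------------------------------------------------
# SNV
# ---------------------------------------------------------------------------

def test_snv_hand_example():
    np.testing.assert_allclose(snv(np.array([1.0, 2.0, 3.0])), [-1, 0, 1])


@settings(max_examples=200, derandomize=True)
@given(
    st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=50).filter(
        lambda v: np.std(v) > 1e-6
    )
)
def test_snv_moments_and_idempotence(values):
    out = snv(np.array(values))
    assert abs(out.mean()) < 1e-10
    assert abs(out.std(ddof=1) - 1.0) < 1e-10
    np.testing.assert_allclose(snv(out), out, atol=1e-9)


@settings(max_examples=100, derandomize=True)
@given(
    st.floats(0.01, 100.0),
    st.floats(-50.0, 50.0),
)
def test_snv_affine_invariance(gain, offset):
    rng = np.random.default_rng(3)
    x = rng.normal(size=40)
    np.testing.assert_allclose(snv(gain * x + offset), snv(x), atol=1e-9)


def test_snv_zero_variance_raises():
    with pytest.raises(DegenerateSpectrumError):
        snv(np.full(10, 3.14))


# ---------------------------------------------------------------------------
# Savitzky-Golay derivative
# ---------------------------------------------------------------------------

def test_sg_exact_on_quadratic():
    wl = np.linspace(1000, 1500, 90)
    out = savgol_derivative(wl**2, 15, 3, deriv=2, spacing_nm=wl[1] - wl[0])
    np.testing.assert_allclose(out, 2.0, atol=1e-8)


def test_sg_exact_on_cubic():
    wl = np.linspace(1000, 1500, 90)
    out = savgol_derivative(wl**3, 15, 3, deriv=2, spacing_nm=wl[1] - wl[0])
    expected = 6.0 * wl[7:-7]
    np.testing.assert_allclose(out, expected, rtol=1e-8)


def test_sg_linearity():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=(2, 60))
    a, b = 2.5, -0.7
    lhs = savgol_derivative(a * x + b * y, 15, 3, 2, 1.0)
    rhs = a * savgol_derivative(x, 15, 3, 2, 1.0) + b * savgol_derivative(
        y, 15, 3, 2, 1.0
    )
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_sg_white_noise_variance_transfer():
    """Empirical output variance matches the coefficient-sum closed form."""
    coeffs = savgol_coeffs(15, 3, deriv=2, delta=1.0)
    expected_var = np.sum(coeffs**2)  # white noise, unit variance
    rng = np.random.default_rng(11)
    draws = rng.normal(size=(10_000, 41))
    out = savgol_derivative(draws, 15, 3, 2, 1.0)
    np.testing.assert_allclose(out.var(), expected_var, rtol=0.05)


def test_sg_window_and_grid_errors():
    with pytest.raises(ValueError, match="window"):
        savgol_derivative(np.arange(8.0), 15, 3, 2, 1.0)
    with pytest.raises(ValueError):
        savgol_derivative(np.arange(30.0), 14, 3, 2, 1.0)
    recipe = PreprocessRecipe(trim_low_nm=None)
    wl = np.concatenate([np.arange(20.0), 25 + np.arange(20.0)])
    with pytest.raises(NonUniformGridError):
        apply_recipe(np.sin(wl), recipe, wl)


def test_sg_drops_edge_half_windows():
    out = savgol_derivative(np.arange(41.0) ** 2, 15, 3, 2, 1.0)
    assert out.size == 41 - 14


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------

def test_trim_boundary_rule():
    wl = 1000 + 5.6 * np.arange(268)
    x = np.ones_like(wl)
    _, trimmed_wl = trim_wavelengths(x, low_nm=1060, wavelengths=wl)
    assert trimmed_wl[0] == pytest.approx(1061.6)  # smallest centre >= 1060
    assert np.all(trimmed_wl >= 1060)


def test_trim_identity_and_empty():
    wl = 1000 + 5.6 * np.arange(30)
    x = np.arange(30.0)
    out, out_wl = trim_wavelengths(x, low_nm=0, high_nm=np.inf, wavelengths=wl)
    np.testing.assert_array_equal(out, x)
    with pytest.raises(ValueError):
        trim_wavelengths(x, low_nm=2600, wavelengths=wl)


def test_trim_cube_updates_axis(tiny_cube):
    out = trim_wavelengths(tiny_cube, low_nm=tiny_cube.wavelengths[2])
    assert out.n_bands == tiny_cube.n_bands - 2
    np.testing.assert_array_equal(out.data, tiny_cube.data[:, :, 2:])


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

class TestExtractProfile:
    def _uniform_cube(self, spectrum, rows=4, cols=5):
        data = np.broadcast_to(spectrum, (rows, cols, spectrum.size)).copy()
        return SpectralCube(
            data=data, wavelengths=1000 + 5.6 * np.arange(spectrum.size)
        )

    def test_identical_pixels_both_forms(self):
        spec = np.linspace(0.2, 0.8, 7)
        cube = self._uniform_cube(spec)
        mask = PixelMask(np.ones((4, 5), bool))
        for form in ("powder", "fragment"):
            np.testing.assert_allclose(extract_profile(cube, mask, form), spec)

    def test_median_robust_to_outliers_mean_is_not(self):
        spec = np.linspace(0.2, 0.8, 7)
        cube = self._uniform_cube(spec, rows=10, cols=10)
        cube.data[0, :10] += 50.0  # 10% gross outlier pixels
        mask = PixelMask(np.ones((10, 10), bool))
        median = extract_profile(cube, mask, "fragment")
        mean = extract_profile(cube, mask, "powder")
        np.testing.assert_allclose(median, spec, atol=1e-12)
        assert np.all(np.abs(mean - spec) > 1.0)

    def test_two_pixel_powder_mean(self):
        u, v = np.arange(5.0), np.arange(5.0)[::-1].copy()
        data = np.stack([u, v])[None, :, :]
        cube = SpectralCube(data=data, wavelengths=1000 + np.arange(5.0))
        mask = PixelMask(np.ones((1, 2), bool))
        np.testing.assert_allclose(
            extract_profile(cube, mask, "powder"), (u + v) / 2
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(9)
        data = rng.uniform(0.1, 0.9, (6, 6, 8))
        wl = 1000 + np.arange(8.0)
        cube = SpectralCube(data=data, wavelengths=wl)
        perm = rng.permutation(36)
        shuffled = SpectralCube(
            data=data.reshape(36, 8)[perm].reshape(6, 6, 8), wavelengths=wl
        )
        mask = PixelMask(np.ones((6, 6), bool))
        for form in ("powder", "fragment"):
            np.testing.assert_allclose(
                extract_profile(cube, mask, form),
                extract_profile(shuffled, mask, form),
            )

    def test_empty_mask_fatal(self, tiny_cube):
        mask = PixelMask(np.zeros((4, 3), bool))
        with pytest.raises(ValueError, match="no pixel"):
            extract_profile(tiny_cube, mask, "powder")


# ---------------------------------------------------------------------------
# Recipe
# ---------------------------------------------------------------------------

def test_recipe_all_steps_disabled_is_identity():
    recipe = PreprocessRecipe(step_order=())
    wl = 1000 + 5.6 * np.arange(50)
    x = np.sin(wl / 100)
    np.testing.assert_array_equal(apply_recipe(x, recipe, wl), x)


def test_recipe_scatter_invariance_bulk():
    """Gain/offset per spectrum must cancel exactly: 1000 random cases."""
    recipe = PreprocessRecipe()
    config = SyntheticConfig()
    wl = config.wavelength_grid
    rng = np.random.default_rng(42)
    base = config.clean_spectrum(10.0)
    gains = rng.uniform(0.5, 2.0, 1000)
    offsets = rng.uniform(-0.2, 0.2, 1000)
    X = base[None, :] * gains[:, None] + offsets[:, None]
    feats, valid, _ = apply_recipe_matrix(X, recipe, wl)
    assert valid.all()
    ref = apply_recipe(base, recipe, wl)
    np.testing.assert_allclose(feats, np.broadcast_to(ref, feats.shape), atol=1e-9)


def test_recipe_feature_count():
    recipe = PreprocessRecipe()
    wl = 1000 + 5.6 * np.arange(268)
    n_trimmed = int(np.sum(wl >= 1060))
    assert recipe.n_output_features(wl) == n_trimmed - (recipe.sg_window - 1)


def test_recipe_json_round_trip():
    recipe = PreprocessRecipe(trim_high_nm=2400.0, absorbance_transform=True)
    again = PreprocessRecipe.from_json(recipe.to_json())
    assert again == recipe


def test_recipe_validation():
    with pytest.raises(ValueError):
        PreprocessRecipe(sg_window=14)
    with pytest.raises(ValueError):
        PreprocessRecipe(sg_polyorder=1, sg_derivative_order=2)
    with pytest.raises(ValueError):
        PreprocessRecipe(step_order=("snv", "mystery"))


def test_recipe_absorbance_flag_changes_output():
    wl = 1000 + 5.6 * np.arange(100)
    x = np.linspace(0.2, 0.8, 100)
    plain = apply_recipe(x, PreprocessRecipe(trim_low_nm=None), wl)
    logged = apply_recipe(
        x,
        PreprocessRecipe(trim_low_nm=None, absorbance_transform=True),
        wl,
    )
    assert not np.allclose(plain, logged)


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def test_polygon_covering_frame_is_all_true(tiny_cube):
    poly = [[-1, -1], [-1, 10], [10, 10], [10, -1]]
    mask = build_background_mask(tiny_cube, polygons=[poly])
    assert mask.grid.all()
    assert mask.provenance == "manual"


def test_two_disjoint_polygons_union():
    data = np.full((10, 10, 4), 0.5)
    cube = SpectralCube(data=data, wavelengths=1000 + np.arange(4.0))
    p1 = [[-0.5, -0.5], [-0.5, 2.5], [2.5, 2.5], [2.5, -0.5]]
    p2 = [[6.5, 6.5], [6.5, 9.5], [9.5, 9.5], [9.5, 6.5]]
    mask = build_background_mask(cube, polygons=[p1, p2])
    expected = np.zeros((10, 10), bool)
    expected[0:3, 0:3] = True
    expected[7:10, 7:10] = True
    np.testing.assert_array_equal(mask.grid, expected)


def test_auto_threshold_recovers_object_footprint(config):
    field = np.full((20, 20), 10.0)
    cube, truth = simulate_cube(
        20, 20, field, background_fraction=0.3, concretion_fraction=0.0,
        config=config, seed=77,
    )
    mask = build_background_mask(cube, threshold=0.1)
    np.testing.assert_array_equal(mask.grid, ~truth["background"].grid)


def test_empty_mask_advises():
    cube = SpectralCube(
        data=np.full((5, 5, 4), 0.01), wavelengths=1000 + np.arange(4.0)
    )
    with pytest.raises(ValueError, match="revise"):
        build_background_mask(cube, threshold=0.5)


class TestConcretionMask:
    def _cube(self, config, frac, seed=5):
        field = np.full((20, 20), 8.0)
        return simulate_cube(
            20, 20, field, background_fraction=0.0, concretion_fraction=frac,
            config=config, seed=seed,
        )

    def test_no_concretions_all_clean(self, config):
        cube, truth = self._cube(config, 0.0)
        mask = build_concretion_mask(
            cube, config.concretion_endmember(), 0.9
        )
        assert mask.grid.all()
        assert truth["concretion"].n_true == 0

    def test_recovers_concretion_footprint(self, config):
        cube, truth = self._cube(config, 0.10)
        mask = build_concretion_mask(
            cube, config.concretion_endmember(), 0.9
        )
        excluded = ~mask.grid
        np.testing.assert_array_equal(excluded, truth["concretion"].grid)

    def test_unreachable_floor_excludes_nothing(self, config):
        cube, _ = self._cube(config, 0.10)
        mask = build_concretion_mask(
            cube, config.concretion_endmember(), 1.0 + 1e-9
        )
        assert mask.grid.all()


def test_mask_png_and_rle_round_trips(tmp_path):
    rng = np.random.default_rng(13)
    mask = PixelMask(rng.random((12, 9)) > 0.5, provenance="concretion")
    mask.to_png(tmp_path / "m.png")
    np.testing.assert_array_equal(
        PixelMask.from_png(tmp_path / "m.png").grid, mask.grid
    )
    mask.to_rle_json(tmp_path / "m.json")
    back = PixelMask.from_rle_json(tmp_path / "m.json")
    np.testing.assert_array_equal(back.grid, mask.grid)
    assert back.provenance == "concretion"
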