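import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sersdx import (
    BandSpec,
    CohortConfig,
    PreprocessConfig,
    airpls_baseline,
    generate_cohort,
    preprocess_pipeline,
    savitzky_golay_smooth,
    vector_normalize,
)

from conftest import make_spectrumset


# ---------------------------------------------------------------------------
# Savitzky-Golay
# ---------------------------------------------------------------------------


def brute_force_savgol(y, window, polyorder):
    """Independent oracle: local least-squares polynomial fit at every point.

    Interior points use the centered window; near the edges the
    polynomial fitted to the first/last full window is evaluated.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    half = window // 2
    out = np.empty(n)
    x = np.arange(n, dtype=float)
    for i in range(n):
        lo, hi = i - half, i + half + 1
        if lo < 0:
            lo, hi = 0, window
        elif hi > n:
            lo, hi = n - window, n
        coeffs = np.polyfit(x[lo:hi] - x[i], y[lo:hi], polyorder)
        out[i] = coeffs[-1]  # polynomial value at the point itself
    return out


@pytest.mark.parametrize("degree", [0, 1, 3, 5])
def test_savgol_reproduces_low_degree_polynomials(degree):
    x = np.linspace(-1, 1, 40)
    rng = np.random.default_rng(degree)
    coeffs = rng.normal(size=degree + 1)
    row = np.polyval(coeffs, x)
    sset = make_spectrumset(row)
    out = savitzky_golay_smooth(sset, window=9, polyorder=5)
    assert np.allclose(out.intensities[0], row, atol=1e-9)


def test_savgol_constant_row_unchanged():
    sset = make_spectrumset(np.full(20, 3.7))
    out = savitzky_golay_smooth(sset, window=9, polyorder=5)
    assert np.allclose(out.intensities[0], 3.7)


def test_savgol_matches_brute_force_local_polyfit():
    rng = np.random.default_rng(17)
    row = rng.normal(size=30)
    out = savitzky_golay_smooth(make_spectrumset(row), window=9, polyorder=5)
    oracle = brute_force_savgol(row, 9, 5)
    assert np.allclose(out.intensities[0], oracle, atol=1e-8)


def test_savgol_is_linear():
    rng = np.random.default_rng(8)
    x, y = rng.normal(size=50), rng.normal(size=50)
    a, b = 2.5, -1.3
    f = lambda v: savitzky_golay_smooth(make_spectrumset(v), 9, 5).intensities[0]
    assert np.allclose(f(a * x + b * y), a * f(x) + b * f(y), atol=1e-10)


def test_savgol_parameter_errors():
    sset = make_spectrumset(np.zeros(20))
    with pytest.raises(ValueError, match="odd"):
        savitzky_golay_smooth(sset, window=8, polyorder=3)
    with pytest.raises(ValueError, match="polyorder"):
        savitzky_golay_smooth(sset, window=9, polyorder=9)
    with pytest.raises(ValueError, match="length"):
        savitzky_golay_smooth(make_spectrumset(np.zeros(5)), window=9, polyorder=2)


# ---------------------------------------------------------------------------
# airPLS
# ---------------------------------------------------------------------------


def brute_force_whittaker(y, w, lam):
    """Dense solve of the weighted Whittaker smoother normal equations."""
    n = y.size
    D = np.diff(np.eye(n), n=2, axis=0)
    return np.linalg.solve(np.diag(w) + lam * D.T @ D, w * y)


def test_airpls_zero_spectrum_gives_zero_baseline():
    baseline, corrected = airpls_baseline(np.zeros(50))
    assert np.allclose(baseline, 0)
    assert np.allclose(corrected, 0)


def test_airpls_first_iteration_matches_dense_whittaker():
    rng = np.random.default_rng(4)
    y = rng.normal(size=40)
    baseline, _ = airpls_baseline(y, lam=10.0, max_iter=1)
    assert np.allclose(baseline, brute_force_whittaker(y, np.ones(40), 10.0), atol=1e-9)


def test_airpls_leaves_pure_smooth_curve_untouched():
    x = np.linspace(600, 1800, 601)
    smooth = 3.0 * np.exp(-0.5 * ((x - 1200) / 350) ** 2)
    _, corrected = airpls_baseline(smooth, lam=1e4)
    assert np.max(np.abs(corrected)) < 0.02 * smooth.max()


def test_airpls_recovers_known_baseline_under_peaks():
    """Synthetic decomposition: baseline + 3 narrow bands -> < 5% RMS off-peak."""
    x = np.linspace(600, 1800, 601)
    true_baseline = 2.0 * np.exp(-0.5 * ((x - 1300) / 255) ** 2) + 4e-4 * (x - 600) + 0.2
    peaks = np.zeros_like(x)
    for center in (800.0, 1100.0, 1500.0):
        peaks += 1.0 * (8.0**2) / ((x - center) ** 2 + 8.0**2)
    estimated, _ = airpls_baseline(true_baseline + peaks, lam=1e4)
    off_peak = np.all(
        np.abs(x[:, None] - np.array([800.0, 1100.0, 1500.0])[None, :]) > 40, axis=1
    )
    rms = np.sqrt(np.mean((estimated - true_baseline)[off_peak] ** 2))
    assert rms < 0.05 * np.sqrt(np.mean(true_baseline[off_peak] ** 2))


def test_airpls_shift_invariance():
    rng = np.random.default_rng(9)
    y = np.abs(rng.normal(size=80)).cumsum() / 10
    base, _ = airpls_baseline(y, lam=100.0)
    base_shifted, _ = airpls_baseline(y + 5.0, lam=100.0)
    # the stopping rule scales with total intensity, so the iteration count
    # may differ by one; the estimates agree to well under the signal scale
    assert np.allclose(base_shifted, base + 5.0, atol=0.05 * np.ptp(y))


def test_airpls_input_validation():
    with pytest.raises(ValueError, match="finite"):
        airpls_baseline(np.array([1.0, np.nan, 2.0, 3.0]))
    with pytest.raises(ValueError, match="lam"):
        airpls_baseline(np.ones(10), lam=0.0)
    with pytest.raises(ValueError, match="length"):
        airpls_baseline(np.ones(3))


# ---------------------------------------------------------------------------
# vector normalization
# ---------------------------------------------------------------------------


@given(st.integers(min_value=0, max_value=2**31 - 1), st.floats(min_value=1e-3, max_value=1e3))
@settings(max_examples=25, deadline=None)
def test_normalize_scale_invariant_and_unit_norm(seed, scale):
    rng = np.random.default_rng(seed)
    row = rng.normal(size=15)
    base = vector_normalize(make_spectrumset(row)).intensities[0]
    scaled = vector_normalize(make_spectrumset(scale * row)).intensities[0]
    assert np.allclose(base, scaled, atol=1e-10)
    assert np.linalg.norm(base) == pytest.approx(1.0)


def test_normalize_idempotent():
    rng = np.random.default_rng(2)
    sset = make_spectrumset(rng.normal(size=(4, 10)))
    once = vector_normalize(sset)
    twice = vector_normalize(once)
    assert np.allclose(once.intensities, twice.intensities)


def test_normalize_zero_row_names_sample():
    sset = make_spectrumset(np.vstack([np.ones(5), np.zeros(5)]), ids=["ok", "empty"])
    with pytest.raises(ValueError, match="empty"):
        vector_normalize(sset)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def test_pipeline_stage_order_and_determinism(default_cohort):
    sset, _ = default_cohort
    trace: list = []
    out1 = preprocess_pipeline(sset, PreprocessConfig(), trace=trace)
    out2 = preprocess_pipeline(sset, PreprocessConfig())
    assert [name for name, _ in trace] == ["savitzky_golay", "airpls", "vector_normalize"]
    assert np.array_equal(out1.intensities, out2.intensities)
    assert np.allclose(np.linalg.norm(out1.intensities, axis=1), 1.0)


def test_pipeline_without_normalization_leaves_norms_free(default_cohort):
    sset, _ = default_cohort
    out = preprocess_pipeline(sset, PreprocessConfig(normalize=False))
    norms = np.linalg.norm(out.intensities, axis=1)
    assert not np.allclose(norms, 1.0)


def test_pipeline_preserves_peak_positions_of_noise_free_bands():
    bands = [BandSpec(c, base_amplitude=1.0) for c in (700.0, 1000.0, 1500.0)]
    cfg = CohortConfig(
        class_sizes={"a": 2},
        bands=bands,
        noise_sd=0.0,
        amplitude_jitter_sigma=0.0,
        replicates_per_sample=1,
    )
    sset, _ = generate_cohort(cfg)
    out = preprocess_pipeline(sset)
    w = out.wavenumbers
    for center in (700.0, 1000.0, 1500.0):
        window = (w >= center - 10) & (w <= center + 10)
        peak_at = w[window][np.argmax(out.intensities[0, window])]
        assert peak_at == center


def test_preprocess_config_validation():
    with pytest.raises(ValueError):
        PreprocessConfig(sg_window=8)
    with pytest.raises(ValueError):
        PreprocessConfig(sg_polyorder=9)
    with pytest.raises(ValueError):
        PreprocessConfig(airpls_lambda=-1.0)
    with pytest.raises(ValueError):
        PreprocessConfig(airpls_tol=1.5)
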