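"""Spectral preprocessing: smoothing, baseline removal, normalization.

The chain applied to every serum SERS spectrum before modelling is

1. Savitzky-Golay smoothing (local least-squares polynomial filtering)
   to suppress shot/detector noise;
2. adaptive iteratively reweighted penalized least squares (airPLS)
   baseline estimation and subtraction, removing the broad
   autofluorescence background of biological samples;
3. vector normalization (unit Euclidean norm per spectrum) to remove
   overall intensity variation between acquisitions.

airPLS estimates the baseline with a Whittaker smoother — minimise
``sum_i w_i (y_i - z_i)^2 + lambda * sum_i (delta^2 z)_i^2`` — whose point
weights are re-estimated each iteration: points rising above the current
baseline (peaks) get zero weight, points below it get exponentially
increasing weight with the iteration count, so the fit is progressively
pulled onto the true background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import splu

from .dataset import SpectrumSet

logger = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    """Parameters of the three-stage chain.

    Defaults: 9-point window / order-5 Savitzky-Golay; airPLS with
    lambda = 1e4, at most 15 reweighting iterations, stopping when the
    summed negative residual falls below 0.1% of the total intensity.
    """

    sg_window: int = 9
    sg_polyorder: int = 5
    airpls_lambda: float = 1e4
    airpls_max_iter: int = 15
    airpls_tol: float = 1e-3
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.airpls_lambda <= 0:
            raise ValueError("airpls_lambda must be > 0")
        if self.airpls_max_iter < 1:
            raise ValueError("airpls_max_iter must be >= 1")
        if not 0 < self.airpls_tol < 1:
            raise ValueError("airpls_tol must be in (0, 1)")


def savitzky_golay_smooth(
    sset: SpectrumSet, window: int = 9, polyorder: int = 5
) -> SpectrumSet:
    """Smooth every spectrum with a Savitzky-Golay filter.

    Endpoints are handled by evaluating the terminal-window polynomial
    fit (``mode="interp"``), so polynomials up to ``polyorder`` pass
    through unchanged over the whole support.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if sset.n_points < window:
        raise ValueError(
            f"window ({window}) exceeds spectrum length ({sset.n_points})"
        )
    smoothed = savgol_filter(sset.intensities, window, polyorder, axis=1, mode="interp")
    return sset.with_intensities(smoothed)


def airpls_baseline(
    spectrum: np.ndarray,
    lam: float = 1e4,
    max_iter: int = 15,
    tol: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate and subtract an airPLS baseline from one spectrum.

    Returns ``(baseline, corrected)`` with ``corrected = spectrum - baseline``.

    Iteration *i* solves the weighted Whittaker problem
    ``(W + lam D'D) z = W y`` with second-difference matrix ``D``; the
    weights are then set to 0 where ``y >= z`` and to
    ``exp(i * |y - z| / |sum of negative residuals|)`` where ``y < z``.
    Stops when the absolute sum of negative residuals drops below
    ``tol`` times the total absolute intensity, or after ``max_iter``
    iterations.
    """
    y = np.asarray(spectrum, dtype=float)
    if y.ndim != 1 or y.size < 4:
        raise ValueError("spectrum must be a 1-D vector of length >= 4")
    if not np.all(np.isfinite(y)):
        raise ValueError("spectrum contains non-finite values")
    if lam <= 0:
        raise ValueError("lam must be > 0")
    p = y.size
    diff = sparse.eye(p, format="csc")
    diff = diff[1:] - diff[:-1]
    penalty = (lam * (diff[1:] - diff[:-1]).T @ (diff[1:] - diff[:-1])).tocsc()

    w = np.ones(p)
    z = y.copy()
    total = np.abs(y).sum()
    for it in range(1, max_iter + 1):
        weight = sparse.diags(w, format="csc")
        z = splu(weight + penalty).solve(w * y)
        d = y - z
        neg = d < 0
        dssn = np.abs(d[neg].sum())
        if total == 0 or dssn < tol * total:
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        # anchor both ends so the exponential reweighting cannot drift there
        w[0] = np.exp(it * np.abs(d[neg]).max() / dssn)
        w[-1] = w[0]
    return z, y - z


def airpls_correct(
    sset: SpectrumSet,
    lam: float = 1e4,
    max_iter: int = 15,
    tol: float = 1e-3,
) -> SpectrumSet:
    """Apply airPLS baseline subtraction to every spectrum in the set."""
    corrected = np.empty_like(sset.intensities)
    for i in range(sset.n_samples):
        _, corrected[i] = airpls_baseline(sset.intensities[i], lam, max_iter, tol)
    return sset.with_intensities(corrected)


def vector_normalize(sset: SpectrumSet) -> SpectrumSet:
    """Scale every spectrum to unit Euclidean norm.

    Raises ``ValueError`` naming the sample if any spectrum is all zero.
    """
    norms = np.linalg.norm(sset.intensities, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise ValueError(
            f"cannot normalize all-zero spectrum of sample "
            f"{sset.sample_ids[zero[0]]!r}"
        )
    return sset.with_intensities(sset.intensities / norms[:, None])


def preprocess_pipeline(
    sset: SpectrumSet,
    config: PreprocessConfig | None = None,
    trace: list | None = None,
) -> SpectrumSet:
    """Run smooth -> baseline-correct -> normalize, in that order.

    ``trace``, if given, collects ``(stage_name, parameters)`` tuples in
    execution order; parameters are also logged.
    """
    config = config or PreprocessConfig()

    def record(stage: str, **params) -> None:
        logger.info("preprocess stage %s: %s", stage, params)
        if trace is not None:
            trace.append((stage, params))

    out = savitzky_golay_smooth(sset, config.sg_window, config.sg_polyorder)
    record("savitzky_golay", window=config.sg_window, polyorder=config.sg_polyorder)
    out = airpls_correct(
        out, config.airpls_lambda, config.airpls_max_iter, config.airpls_tol
    )
    record(
        "airpls",
        lam=config.airpls_lambda,
        max_iter=config.airpls_max_iter,
        tol=config.airpls_tol,
    )
    if config.normalize:
        out = vector_normalize(out)
        record("vector_normalize")
    return out
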