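"""Synthetic serum-SERS cohort generator.

Serum SERS spectra in the 600-1800 cm^-1 fingerprint region are well
described as a sum of narrow vibrational bands riding on a broad, smooth
autofluorescence background, with instrument noise on top.  The generator
emulates a three-class diagnostic cohort (healthy controls, gallbladder
stone and gallbladder polyp patients) in which a subset of bands carries
class-dependent intensity, the structure the downstream discriminant
analysis is designed to detect.

Each raw replicate spectrum is

    sum over bands of  Lorentzian(center, fwhm) * base_amplitude
                       * class_multiplier * lognormal jitter
    + per-sample baseline (broad Gaussian hump + linear slope)
    + additive Gaussian noise,

and the replicates of one sample are averaged into its final spectrum,
mirroring the common practice of acquiring several technical replicates
per serum droplet and analysing their mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .dataset import SpectrumSet

HEALTHY = "healthy"
STONE = "gb_stone"
POLYP = "gb_polyp"

#: Default cohort composition: 72 healthy, 51 stone, 25 polyp (148 samples).
DEFAULT_CLASS_SIZES: dict[str, int] = {HEALTHY: 72, STONE: 51, POLYP: 25}


@dataclass
class BandSpec:
    """One Lorentzian band and its class-specific intensity factors.

    ``class_multipliers`` scale ``base_amplitude`` per class; a class
    missing from the map gets factor 1.
    """

    center: float
    width: float = 16.0  # FWHM, cm^-1
    base_amplitude: float = 1.0
    class_multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band {self.center}: width must be > 0")
        if self.base_amplitude < 0:
            raise ValueError(f"band {self.center}: base_amplitude must be >= 0")
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError(f"band {self.center}: multipliers must be > 0")

    def multiplier(self, label: str) -> float:
        return self.class_multipliers.get(label, 1.0)

    def profile(self, grid: np.ndarray) -> np.ndarray:
        """Unit-peak Lorentzian on the grid."""
        hw = self.width / 2.0
        return hw**2 / ((grid - self.center) ** 2 + hw**2)


@dataclass
class BaselineConfig:
    """Broad smooth background: Gaussian hump plus linear slope.

    ``amplitude`` is the mean hump height; each sample draws its own
    height (lognormal, sd ``amplitude_jitter``) and slope (normal around
    ``slope``), emulating sample-to-sample autofluorescence variation.
    """

    amplitude: float = 2.0
    center: float = 1300.0
    width: float = 600.0  # FWHM of the hump, cm^-1
    slope: float = 5e-4  # intensity per cm^-1
    offset: float = 0.2
    amplitude_jitter: float = 0.3
    slope_jitter: float = 0.3

    def curve(self, grid: np.ndarray, amplitude: float, slope: float) -> np.ndarray:
        sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        hump = amplitude * np.exp(-0.5 * ((grid - self.center) / sigma) ** 2)
        return hump + slope * (grid - grid[0]) + self.offset


def default_serum_bands(effect_scale: float = 1.0) -> list[BandSpec]:
    """The 11 reference serum-SERS bands with default class effects.

    Band positions are the characteristic serum peaks at 637, 722, 810,
    888, 1003, 1134, 1203, 1333, 1432, 1557 and 1652 cm^-1 (assignments
    in :data:`sersdx.peaks.PEAK_ASSIGNMENTS`).  Default multipliers
    encode the qualitative group differences the analysis targets:

    * stone patients depressed relative to healthy at 888 (glutathione);
    * polyp patients elevated relative to healthy at 1203 (phenylalanine);
    * stone and polyp separated at 637, 722, 1203, 1432 and 1652;
    * polyp additionally separated from healthy at 1134 (D-mannose);
    * no class effect at 810, 1003, 1333 or 1557.

    The per-class up/down effects are chosen to be approximately
    norm-balanced (each class redistributes band intensity rather than
    changing the total spectral energy).  This mirrors real SERS, where
    absolute intensity carries no analyte information, and it keeps
    vector normalization from leaking class differences into the
    null-effect bands.

    ``effect_scale`` scales every multiplier's deviation from 1
    (``m -> 1 + effect_scale * (m - 1)``); 0 removes all class effects.
    """

    def mult(h: float, s: float, p: float) -> dict[str, float]:
        return {
            HEALTHY: 1.0 + effect_scale * (h - 1.0),
            STONE: 1.0 + effect_scale * (s - 1.0),
            POLYP: 1.0 + effect_scale * (p - 1.0),
        }

    bands = [
        BandSpec(637.0, base_amplitude=0.55, class_multipliers=mult(1.0, 1.20, 0.80)),
        BandSpec(722.0, base_amplitude=0.75, class_multipliers=mult(1.0, 0.78, 1.20)),
        BandSpec(810.0, base_amplitude=0.40, class_multipliers=mult(1.0, 1.0, 1.0)),
        BandSpec(888.0, base_amplitude=0.50, class_multipliers=mult(1.0, 0.70, 1.0)),
        BandSpec(1003.0, base_amplitude=1.00, class_multipliers=mult(1.0, 1.0, 1.0)),
        BandSpec(1134.0, base_amplitude=0.55, class_multipliers=mult(1.0, 1.0, 0.75)),
        BandSpec(1203.0, base_amplitude=0.60, class_multipliers=mult(1.0, 1.20, 1.35)),
        BandSpec(1333.0, base_amplitude=0.50, class_multipliers=mult(1.0, 1.0, 1.0)),
        BandSpec(1432.0, base_amplitude=0.45, class_multipliers=mult(1.0, 1.0, 0.75)),
        BandSpec(1557.0, base_amplitude=0.50, class_multipliers=mult(1.0, 1.0, 1.0)),
        BandSpec(1652.0, base_amplitude=0.65, class_multipliers=mult(1.0, 1.10, 0.70)),
    ]
    return bands


@dataclass
class CohortConfig:
    """Full recipe for one synthetic cohort; deterministic given ``seed``."""

    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES)
    )
    grid_start: float = 600.0
    grid_stop: float = 1800.0
    grid_step: float = 2.0
    bands: list[BandSpec] = field(default_factory=default_serum_bands)
    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    noise_sd: float = 0.03
    replicates_per_sample: int = 5
    amplitude_jitter_sigma: float = 0.15  # lognormal sigma of per-sample band jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.class_sizes.values()):
            raise ValueError("class sizes must be positive")
        if not self.grid_start < self.grid_stop:
            raise ValueError("grid_start must be < grid_stop")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be > 0")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_stop - self.grid_start) / self.grid_step)) + 1
        return self.grid_start + self.grid_step * np.arange(n)


@dataclass
class GroundTruth:
    """Per-sample generative record for parameter-recovery tests."""

    labels: list[str]
    band_centers: list[float]
    band_multipliers: dict[str, list[float]]  # class -> multiplier per band
    baseline_amplitudes: list[float]
    baseline_slopes: list[float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def generate_cohort(config: CohortConfig | None = None) -> tuple[SpectrumSet, GroundTruth]:
    """Draw one cohort; returns the replicate-averaged spectra and the truth.

    Raises ``ValueError`` naming the band if any band center falls outside
    the wavenumber grid.
    """
    config = config or CohortConfig()
    grid = config.grid()
    for band in config.bands:
        if not (grid[0] <= band.center <= grid[-1]):
            raise ValueError(
                f"band at {band.center} cm^-1 lies outside the grid "
                f"[{grid[0]}, {grid[-1]}] cm^-1"
            )
    rng = np.random.default_rng(config.seed)
    profiles = np.vstack([b.profile(grid) for b in config.bands])  # (bands, p)

    labels: list[str] = []
    ids: list[str] = []
    rows: list[np.ndarray] = []
    truth_amp: list[float] = []
    truth_slope: list[float] = []
    bl = config.baseline
    for label, count in config.class_sizes.items():
        base = np.array(
            [b.base_amplitude * b.multiplier(label) for b in config.bands]
        )
        for k in range(count):
            jitter = np.exp(
                rng.normal(0.0, config.amplitude_jitter_sigma, size=len(config.bands))
            )
            amps = base * jitter
            bl_amp = bl.amplitude * float(np.exp(rng.normal(0.0, bl.amplitude_jitter)))
            bl_slope = bl.slope * float(1.0 + rng.normal(0.0, bl.slope_jitter))
            clean = amps @ profiles + bl.curve(grid, bl_amp, bl_slope)
            reps = clean + rng.normal(
                0.0, config.noise_sd, size=(config.replicates_per_sample, grid.size)
            ) if config.noise_sd > 0 else np.tile(clean, (config.replicates_per_sample, 1))
            rows.append(reps.mean(axis=0))
            labels.append(label)
            ids.append(f"{label}_{k + 1:03d}")
            truth_amp.append(bl_amp)
            truth_slope.append(bl_slope)

    sset = SpectrumSet(
        wavenumbers=grid,
        intensities=np.vstack(rows),
        labels=np.array(labels, dtype=object),
        sample_ids=np.array(ids, dtype=object),
    )
    truth = GroundTruth(
        labels=labels,
        band_centers=[b.center for b in config.bands],
        band_multipliers={
            c: [b.multiplier(c) for b in config.bands] for c in config.class_sizes
        },
        baseline_amplitudes=truth_amp,
        baseline_slopes=truth_slope,
    )
    return sset, truth
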