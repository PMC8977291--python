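"""Synthetic input generators.

Everything the pipeline consumes can be generated here: piecewise-smooth
phantoms with optional lesions, their (optionally noisy) k-space data,
mono-exponential DWI signal series, gamma-variate time-intensity curves, and
two-group diagnostic cohorts.  All generators are bit-reproducible under a
fixed seed.

Intensities live on the [0, 255] scale used by the PSNR metric.  ADC values
are expressed in 1e-3 mm^2/s throughout (the physiological scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionSpec:
    """A round lesion: ``center`` is (row, col) in pixels, ``radius`` in
    pixels (scalar or (r_row, r_col) for an ellipse), ``contrast`` the
    additive intensity change inside the lesion."""

    center: tuple[float, float]
    radius: float | tuple[float, float]
    contrast: float = 60.0

    @property
    def radii(self) -> tuple[float, float]:
        r = self.radius
        if np.isscalar(r):
            return (float(r), float(r))
        return (float(r[0]), float(r[1]))


@dataclass
class Phantom:
    """A 2D grayscale test image plus ground-truth lesion annotation."""

    image: np.ndarray                 # float64, [0, 255]
    lesion_mask: np.ndarray           # bool, same shape
    lesion_params: list[LesionSpec]
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape


@dataclass
class KSpaceData:
    """Complex frequency-domain samples on an M x N grid (orthonormal FFT
    convention).  Entries are meaningful only where a companion mask is
    true once undersampled."""

    values: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DWISeries:
    """Per-voxel diffusion-weighted signals at increasing b-values.

    ``b_values`` are in s/mm^2; ``true_adc`` (synthetic only) in
    1e-3 mm^2/s."""

    b_values: np.ndarray
    signals: np.ndarray
    true_adc: float | None = None

    def __post_init__(self):
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.b_values.size < 2:
            raise ValueError("a DWI series needs at least 2 b-values")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing")
        if self.signals.shape != self.b_values.shape:
            raise ValueError("signals and b_values must have equal length")


@dataclass
class TimeIntensityCurve:
    """Signal intensity sampled over time after contrast injection."""

    times: np.ndarray
    signal: np.ndarray
    baseline_index: int = 0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.signal.shape != self.times.shape:
            raise ValueError("signal and times must have equal length")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group diagnostic cohort.

    ``adc_mean``/``adc_sd``/``p_correct`` are pairs ordered like
    ``group_names`` (default: control first, algorithm second).  ADC
    parameters are in 1e-3 mm^2/s."""

    n_per_group: int
    adc_mean: tuple[float, float]
    adc_sd: tuple[float, float]
    p_correct: tuple[float, float] = (1.0, 1.0)
    seed: int = 0
    group_names: tuple[str, str] = ("control", "algorithm")

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be at least 2")
        if any(s <= 0 for s in self.adc_sd):
            raise ValueError("adc_sd entries must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.p_correct):
            raise ValueError("p_correct entries must lie in [0, 1]")


# --------------------------------------------------------------------------
# phantom
# --------------------------------------------------------------------------

def make_phantom(
    height: int,
    width: int,
    lesions: Sequence[LesionSpec] = (),
    seed: int = 0,
    edge_softness: float = 3.0,
    texture_amplitude: float = 25.0,
    texture_period: float = 5.0,
    random_field_amplitude: float = 2.0,
) -> Phantom:
    """Build a piecewise-smooth phantom: a shaded body ellipse containing an
    annular bright "wall" around a dark lumen, overlaid with a fine ring
    texture, plus optional lesions.

    The design is deliberately band-structured: region boundaries are
    softened by ``edge_softness`` (a Gaussian blur, emulating the
    band-limited point-spread of an acquisition), while the concentric
    ``texture_period``-pixel ring texture concentrates energy in a mid/high
    spatial-frequency annulus that undersampling actually destroys.  The
    texture is locally a smooth oriented oscillation, i.e. well captured by
    small-patch sparse models.  Deterministic per seed.

    Parameters
    ----------
    height, width : int
        Grid size, both >= 32.
    lesions : sequence of LesionSpec
        Lesions to stamp into the image; each must lie inside the grid.
    seed : int
        Seeds the low-frequency random shading field.
    edge_softness : float
        Gaussian sigma (pixels) applied to the piecewise region structure.
    texture_amplitude, texture_period : float
        Amplitude and pixel period of the concentric ring texture
        (``texture_amplitude = 0`` disables it).
    random_field_amplitude : float
        Std of the smooth random shading added inside the body.

    Returns
    -------
    Phantom
        Image in [0, 255] with a boolean lesion mask.
    """
    if height < 32 or width < 32:
        raise ValueError("phantom grid must be at least 32x32")

    yy = (np.arange(height)[:, None] - (height - 1) / 2) / (height / 2)
    xx = (np.arange(width)[None, :] - (width - 1) / 2) / (width / 2)

    r_body = (xx / 0.92) ** 2 + (yy / 0.85) ** 2
    r_wall = (xx / 0.62) ** 2 + (yy / 0.55) ** 2
    r_lumen = (xx / 0.42) ** 2 + (yy / 0.36) ** 2

    image = np.full((height, width), 12.0)
    body = r_body < 1.0
    wall = (r_wall < 1.0) & (r_lumen >= 1.0)
    lumen = r_lumen < 1.0

    # smooth shading inside each region; TV-style priors see gradients here.
    # region contrasts are mild: the hard edges would otherwise dominate the
    # spectrum and the patch-approximation error budget
    shade = 25.0 * (xx + 0.6 * yy) + 30.0 * (1.0 - np.minimum(r_body, 1.0))
    image[body] = 130.0 + shade[body]
    image[wall] = 165.0 + 0.6 * shade[wall]
    image[lumen] = 80.0 + 0.3 * shade[lumen]

    if random_field_amplitude > 0:
        rng = np.random.default_rng(seed)
        field = rng.standard_normal((height, width))
        field = gaussian_filter(field, sigma=min(height, width) / 16.0)
        field *= random_field_amplitude / max(field.std(), 1e-12)
        image[body] += field[body]

    if edge_softness > 0:
        image = gaussian_filter(image, edge_softness)

    if texture_amplitude > 0:
        window = gaussian_filter(body.astype(float), 3.0)
        rad = np.hypot(np.arange(height)[:, None] - height / 2,
                       np.arange(width)[None, :] - width / 2)
        image = image + (texture_amplitude
                         * np.cos(2 * np.pi * rad / texture_period) * window)

    lesion_mask = np.zeros((height, width), dtype=bool)
    lesion_list = list(lesions)
    for spec in lesion_list:
        cr, cc = spec.center
        rr, rc = spec.radii
        if rr <= 0 or rc <= 0:
            raise ValueError(f"lesion radius must be positive, got {spec.radius}")
        if cr - rr < 0 or cr + rr > height - 1 or cc - rc < 0 or cc + rc > width - 1:
            raise ValueError(
                f"lesion at {spec.center} with radii {spec.radii} falls outside "
                f"the {height}x{width} grid"
            )
        dist = ((np.arange(height)[:, None] - cr) / rr) ** 2 + (
            (np.arange(width)[None, :] - cc) / rc
        ) ** 2
        inside = dist < 1.0
        # lesions get only a light softening so their nominal contrast is
        # preserved under direct pixel averaging
        soft = inside.astype(float)
        if edge_softness > 0:
            soft = gaussian_filter(soft, min(edge_softness, 1.0))
        image = image + spec.contrast * soft
        lesion_mask |= inside

    np.clip(image, 0.0, 255.0, out=image)
    return Phantom(image=image, lesion_mask=lesion_mask,
                   lesion_params=lesion_list, seed=seed)


# --------------------------------------------------------------------------
# k-space
# --------------------------------------------------------------------------

def simulate_kspace(image: np.ndarray) -> KSpaceData:
    """Fully sampled k-space of a real image: orthonormal 2D FFT.

    With the orthonormal convention the inverse transform recovers the image
    to round-off and Parseval's identity holds exactly.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    return KSpaceData(values=np.fft.fft2(image, norm="ortho"))


def inverse_kspace(kspace: KSpaceData | np.ndarray) -> np.ndarray:
    """Inverse orthonormal 2D FFT; returns the complex image."""
    values = kspace.values if isinstance(kspace, KSpaceData) else np.asarray(kspace)
    return np.fft.ifft2(values, norm="ortho")


def add_gaussian_noise(kspace: KSpaceData, sigma: float, seed: int = 0) -> KSpaceData:
    """Add i.i.d. complex Gaussian noise (``sigma`` per real/imag component)
    to every k-space sample.  ``sigma = 0`` returns the input unchanged."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0:
        return KSpaceData(values=kspace.values.copy())
    rng = np.random.default_rng(seed)
    shape = kspace.values.shape
    noise = rng.normal(0.0, sigma, shape) + 1j * rng.normal(0.0, sigma, shape)
    return KSpaceData(values=kspace.values + noise)


# --------------------------------------------------------------------------
# DWI / TIC
# --------------------------------------------------------------------------

DEFAULT_B_VALUES = (50.0, 400.0, 800.0)


def simulate_dwi_series(
    s0: float,
    adc: float,
    b_values: Sequence[float] = DEFAULT_B_VALUES,
    sigma: float = 0.0,
    seed: int = 0,
) -> DWISeries:
    """Mono-exponential DWI decay ``S(b) = s0 * exp(-adc * b * 1e-3)``.

    ``b_values`` in s/mm^2, ``adc`` in 1e-3 mm^2/s; optional additive
    Gaussian noise of standard deviation ``sigma``.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if adc <= 0:
        raise ValueError("adc must be positive")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    b = np.asarray(b_values, dtype=float)
    signals = s0 * np.exp(-adc * b * 1e-3)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, sigma, b.shape)
    return DWISeries(b_values=b, signals=signals, true_adc=adc)


def simulate_tic(
    baseline: float,
    peak: float,
    times: Sequence[float],
    peak_time: float,
    sigma: float = 0.0,
    seed: int = 0,
    shape: float = 3.0,
) -> TimeIntensityCurve:
    """Gamma-variate time-intensity curve: rise from ``baseline`` to ``peak``
    at ``peak_time``, then washout.

    The default frame spacing in generated protocols is 30 s.  When
    ``peak_time`` coincides with a sample, the noiseless maximum equals
    ``peak`` exactly.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if peak < baseline:
        raise ValueError("peak must be >= baseline")
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if not (t[0] < peak_time <= t[-1]):
        raise ValueError(
            f"peak_time {peak_time} lies outside the sampled window "
            f"({t[0]}, {t[-1]}]"
        )
    t0 = t[0]
    tau = np.clip((t - t0) / (peak_time - t0), 0.0, None)
    with np.errstate(invalid="ignore"):
        bolus = tau ** shape * np.exp(shape * (1.0 - tau))
    signal = baseline + (peak - baseline) * bolus
    if sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, sigma, t.shape)
    return TimeIntensityCurve(times=t, signal=signal, baseline_index=0)


def default_tic_times(n_frames: int = 12, spacing: float = 30.0) -> np.ndarray:
    """Frame times for a dynamic series scanned every ``spacing`` seconds."""
    return spacing * np.arange(1, n_frames + 1)


# --------------------------------------------------------------------------
# cohorts
# --------------------------------------------------------------------------

def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a two-group diagnostic table.

    Returns a DataFrame with columns ``patient_id, group, adc, correct``:
    ADC drawn per-group Gaussian truncated at zero (resampled), correctness
    flags Bernoulli(p_correct).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    pid = 1
    for g, name in enumerate(spec.group_names):
        adc = rng.normal(spec.adc_mean[g], spec.adc_sd[g], spec.n_per_group)
        bad = adc <= 0
        while np.any(bad):  # truncate at zero by resampling
            adc[bad] = rng.normal(spec.adc_mean[g], spec.adc_sd[g], int(bad.sum()))
            bad = adc <= 0
        correct = (rng.random(spec.n_per_group) < spec.p_correct[g]).astype(int)
        for i in range(spec.n_per_group):
            rows.append((f"P{pid:03d}", name, float(adc[i]), int(correct[i])))
            pid += 1
    return pd.DataFrame(rows, columns=["patient_id", "group", "adc", "correct"])
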