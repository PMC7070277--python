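"""Signal preprocessing: band-pass filtering, windowed features, angle
resampling, min-max normalization and wavelet denoising.

The processing chain mirrors a standard multi-source gait pipeline: raw
sEMG (2000 Hz) is band-pass filtered to the useful 20–500 Hz band and
reduced to RMS features over non-overlapping 20-sample windows; plantar
pressure is reduced to 20-sample window means; joint angles are fitted
with a least-squares cubic spline (one knot per 20 raw samples) and
resampled onto the uniform 100 Hz feature clock. All channels are min-max
normalized into [0, 1] before entering the regression network, and
predictions are denormalized back to degrees afterwards.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import interpolate, signal as _signal

logger = logging.getLogger(__name__)

__all__ = [
    "BandpassSpec",
    "FilterDesignError",
    "NormalizationParams",
    "FeatureSeries",
    "design_bandpass",
    "apply_filter",
    "windowed_rms",
    "windowed_mean",
    "resample_angles",
    "minmax_normalize",
    "minmax_denormalize",
    "wavelet_lowpass",
    "wavelet_denoise",
]


class FilterDesignError(ValueError):
    """Raised when a band-pass specification cannot be realized."""


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass design specification.

    Defaults are the standard sEMG band: pass band [20, 500] Hz with at
    most 3 dB ripple, stop edges at 10 and 570 Hz with at least 20 dB
    attenuation, at a 2000 Hz sampling rate.
    """

    pass_lo: float = 20.0
    pass_hi: float = 500.0
    stop_lo: float = 10.0
    stop_hi: float = 570.0
    pass_atten_max: float = 3.0
    stop_atten_min: float = 20.0
    sample_rate: float = 2000.0

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2.0
        if not (0 < self.stop_lo < self.pass_lo < self.pass_hi < self.stop_hi < nyq):
            raise FilterDesignError(
                "band edges must satisfy 0 < stop_lo < pass_lo < pass_hi < "
                f"stop_hi < Nyquist ({nyq} Hz); got "
                f"({self.stop_lo}, {self.pass_lo}, {self.pass_hi}, {self.stop_hi})"
            )
        if not self.pass_atten_max < self.stop_atten_min:
            raise FilterDesignError(
                "pass_atten_max must be smaller than stop_atten_min; got "
                f"{self.pass_atten_max} dB >= {self.stop_atten_min} dB"
            )


@dataclass
class DigitalFilter:
    """Cascaded second-order-sections filter with its design metadata."""

    sos: np.ndarray
    order: int
    spec: BandpassSpec

    def frequency_response(self, freqs_hz: np.ndarray) -> np.ndarray:
        """Complex response H(f) of a single (forward-only) pass."""
        _, h = _signal.sosfreqz(self.sos, worN=np.atleast_1d(freqs_hz), fs=self.spec.sample_rate)
        return h


def design_bandpass(spec: BandpassSpec = BandpassSpec()) -> DigitalFilter:
    """Design the minimal-order Butterworth band-pass meeting ``spec``.

    The returned order is the analog-prototype (lowpass-equivalent) order;
    the realized digital band-pass has twice as many poles. Coefficients
    are returned as second-order sections for numerical stability.
    """
    try:
        order, wn = _signal.buttord(
            [spec.pass_lo, spec.pass_hi],
            [spec.stop_lo, spec.stop_hi],
            gpass=spec.pass_atten_max,
            gstop=spec.stop_atten_min,
            fs=spec.sample_rate,
        )
        sos = _signal.butter(order, wn, btype="bandpass", output="sos", fs=spec.sample_rate)
    except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
        raise FilterDesignError(f"infeasible band-pass specification: {exc}") from exc
    if not np.all(np.isfinite(sos)):
        raise FilterDesignError("filter design produced non-finite coefficients")
    return DigitalFilter(sos=sos, order=int(order), spec=spec)


def apply_filter(filt: DigitalFilter, x: np.ndarray) -> np.ndarray:
    """Zero-phase (forward-backward) application of a designed filter.

    Forward-backward filtering cancels the phase response, which keeps the
    filtered sEMG time-locked to the angle targets; the price is that the
    magnitude response is applied twice.
    """
    x = np.asarray(x, dtype=float)
    # sosfiltfilt needs padlen+1 samples; 3x the pole count is a safe floor.
    min_len = 6 * filt.order + 1
    if x.size < min_len:
        raise ValueError(
            f"signal of length {x.size} too short for zero-phase filtering "
            f"(need > {min_len - 1} samples for a filter of order {filt.order})"
        )
    return _signal.sosfiltfilt(filt.sos, x)


def _windowed(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 0:
        raise ValueError(f"window must be >= 1, got {window}")
    x = np.asarray(x, dtype=float)
    n = (x.size // window) * window
    return x[:n].reshape(-1, window)


def windowed_rms(x: np.ndarray, window: int = 20) -> np.ndarray:
    """Root-mean-square over non-overlapping windows.

    RMS = sqrt((1/N) sum x_i^2) per window; the trailing partial window is
    discarded. Squaring makes explicit rectification a no-op, so the usual
    "rectify then filter" sEMG step is absorbed here.
    """
    blocks = _windowed(x, window)
    if blocks.size == 0:
        return np.empty(0)
    return np.sqrt(np.mean(blocks**2, axis=1))


def windowed_mean(x: np.ndarray, window: int = 20) -> np.ndarray:
    """Arithmetic mean over non-overlapping windows (pressure features)."""
    blocks = _windowed(x, window)
    if blocks.size == 0:
        return np.empty(0)
    return np.mean(blocks, axis=1)


@dataclass
class FeatureSeries:
    """A uniformly sampled feature channel on the common feature clock."""

    t: np.ndarray
    values: np.ndarray
    channel_name: str = ""
    units: str = ""

    def validate(self, rate_hz: float = 100.0) -> None:
        dt = np.diff(self.t)
        if dt.size and np.max(np.abs(dt - 1.0 / rate_hz)) > 1e-9:
            raise ValueError(f"{self.channel_name}: spacing is not uniform 1/{rate_hz} s")


def resample_angles(
    t: np.ndarray,
    angle: np.ndarray,
    out_rate: float = 100.0,
    fit_window: int = 20,
    channel_name: str = "",
) -> FeatureSeries:
    """Fit a least-squares cubic spline to a raw angle channel and resample
    it on a uniform ``out_rate`` grid.

    The spline has one interior knot per ``fit_window`` raw samples, i.e.
    the angle signal is fitted blockwise into a smooth time curve rather
    than interpolated through every noisy sample. The spline space contains
    all cubic polynomials, so clean polynomial inputs are reproduced
    exactly (to rounding).
    """
    t = np.asarray(t, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time stamps must be strictly increasing")
    if fit_window < 1:
        raise ValueError("fit_window must be >= 1")

    knots = t[fit_window::fit_window]
    knots = knots[knots < t[-1]]
    if knots.size and t.size >= 8:
        spline = interpolate.LSQUnivariateSpline(t, angle, knots, k=3)
    else:
        k = min(3, t.size - 1)
        spline = interpolate.UnivariateSpline(t, angle, k=k, s=0)

    n_out = int(np.floor((t[-1] - t[0]) * out_rate)) + 1
    t_out = t[0] + np.arange(n_out) / out_rate
    return FeatureSeries(t=t_out, values=spline(t_out), channel_name=channel_name, units="deg")


class DegenerateRangeError(ValueError):
    """Raised when min-max normalization meets a constant channel."""


@dataclass
class NormalizationParams:
    """Per-channel (min, max) bounds for the [0, 1] min-max mapping."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for ch, (lo, hi) in self.bounds.items():
            if not hi > lo:
                raise DegenerateRangeError(f"channel {ch!r}: max ({hi}) must exceed min ({lo})")

    def __getitem__(self, ch: str) -> tuple[float, float]:
        return self.bounds[ch]

    def __contains__(self, ch: str) -> bool:
        return ch in self.bounds

    def to_json(self) -> str:
        return json.dumps({ch: list(b) for ch, b in sorted(self.bounds.items())})

    @classmethod
    def from_json(cls, text: str) -> "NormalizationParams":
        raw = json.loads(text)
        return cls({ch: (float(lo), float(hi)) for ch, (lo, hi) in raw.items()})

    @classmethod
    def from_data(cls, channels: dict[str, np.ndarray]) -> "NormalizationParams":
        bounds = {}
        for ch, x in channels.items():
            lo, hi = float(np.min(x)), float(np.max(x))
            if not hi > lo:
                raise DegenerateRangeError(f"channel {ch!r} is constant ({lo}); cannot normalize")
            bounds[ch] = (lo, hi)
        return cls(bounds)


def minmax_normalize(
    x: np.ndarray, bounds: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Map a signal into [0, 1] via (x - min) / (max - min).

    If ``bounds`` is None the bounds are computed from the data (training
    channels); if given (test channels normalized with training bounds),
    out-of-range values are clipped into [0, 1].
    """
    x = np.asarray(x, dtype=float)
    fitted = bounds is None
    if fitted:
        lo, hi = float(np.min(x)), float(np.max(x))
        if not hi > lo:
            raise DegenerateRangeError(f"constant signal (value {lo}); cannot normalize")
    else:
        lo, hi = bounds
        if not hi > lo:
            raise DegenerateRangeError(f"max ({hi}) must exceed min ({lo})")
    xn = (x - lo) / (hi - lo)
    if not fitted:
        xn = np.clip(xn, 0.0, 1.0)
    return xn, (lo, hi)


def minmax_denormalize(xn: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    """Exact algebraic inverse of :func:`minmax_normalize`."""
    lo, hi = bounds
    if not hi > lo:
        raise DegenerateRangeError(f"max ({hi}) must exceed min ({lo})")
    return np.asarray(xn, dtype=float) * (hi - lo) + lo


def _effective_level(n: int, wavelet: str, levels: int) -> int:
    max_level = pywt.dwt_max_level(n, wavelet)
    if levels > max_level:
        logger.warning(
            "signal of length %d supports at most a level-%d %s decomposition; "
            "reducing requested level %d",
            n, max_level, wavelet, levels,
        )
        return max_level
    return levels


def wavelet_lowpass(x: np.ndarray, wavelet: str = "coif5", levels: int = 6) -> np.ndarray:
    """Approximation-only wavelet reconstruction (aggressive low-pass).

    Decomposes to ``levels`` scales, zeroes every detail band and
    reconstructs from the deepest approximation alone, keeping only the
    0 .. fs/2^(levels+1) band. Periodized boundary handling makes the
    operation an exact orthogonal projection whenever the signal length is
    divisible by 2**levels (idempotent, never energy-increasing). Levels
    are reduced (with a logged warning) when the signal is too short for
    the requested depth.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    level = _effective_level(x.size, wavelet, levels)
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    coeffs = [coeffs[0]] + [np.zeros_like(d) for d in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet, mode="periodization")[: x.size]


def wavelet_denoise(
    x: np.ndarray,
    wavelet: str = "coif5",
    levels: int = 6,
    threshold_mode: str = "hard",
) -> np.ndarray:
    """Wavelet shrinkage denoising (coif5, level 6 by default).

    Detail coefficients at every scale are thresholded at the universal
    threshold sigma * sqrt(2 ln n), with sigma estimated from the
    finest-scale details by the median absolute deviation. Unlike
    :func:`wavelet_lowpass` this removes sudden spikes and wide-band noise
    while leaving the (large-coefficient) signal content intact, which is
    what the pressure-feature cleanup and prediction smoothing stages need:
    gait signals at 100 Hz keep their ~1 Hz fundamental and its harmonics.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x.copy()
    level = _effective_level(x.size, wavelet, levels)
    if level < 1:
        return x.copy()
    coeffs = pywt.wavedec(x, wavelet, level=level, mode="periodization")
    sigma = float(np.median(np.abs(coeffs[-1]))) / 0.6745
    if sigma == 0.0:
        return pywt.waverec(coeffs, wavelet, mode="periodization")[: x.size]
    thr = sigma * np.sqrt(2.0 * np.log(x.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        coeffs = [coeffs[0]] + [pywt.threshold(d, thr, threshold_mode) for d in coeffs[1:]]
    return pywt.waverec(coeffs, wavelet, mode="periodization")[: x.size]
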