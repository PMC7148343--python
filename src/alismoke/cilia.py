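"""Per-pixel ciliary beat-frequency (CBF) mapping from video stacks.

High-speed videomicroscopy of an air-liquid-interface culture records
beating cilia as a periodic intensity modulation at each pixel.  Each
pixel's temporal trace is detrended, transformed to a one-sided power
spectrum, and searched for a dominant peak inside a physiological
frequency band.  A pixel is called *active* when the in-band peak power
exceeds ``snr_threshold`` times the median in-band power; the peak's
frequency is then that pixel's CBF.  Mapping the result back to image
space yields a frequency map from which the area covered by actively
beating cilia and the mean CBF are summarized.

The activity criterion is a deliberate, tunable package choice (the
peak-to-median power ratio); its false-positive rate on pure-noise traces
is characterized empirically in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VideoStack",
    "SpectralConfig",
    "FrequencyMap",
    "CiliaSummary",
    "pixel_spectrum",
    "detect_meaningful_frequency",
    "compute_frequency_map",
    "summarize_cilia",
    "render_false_color",
]

#: minimum number of frames for a usable spectrum
MIN_FRAMES = 64


@dataclass(frozen=True)
class VideoStack:
    """A T-frame grayscale image sequence with its acquisition frame rate."""

    frames: np.ndarray  # (T, H, W) float
    fps: float  # Hz

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"frames must be a (T, H, W) array, got shape {frames.shape}")
        if frames.shape[0] < MIN_FRAMES:
            raise ValueError(
                f"need at least {MIN_FRAMES} frames for spectral analysis, got {frames.shape[0]}"
            )
        if not np.isfinite(frames).all():
            raise ValueError("frames contain non-finite intensities")
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(height, width) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]


@dataclass(frozen=True)
class SpectralConfig:
    """Settings for the per-pixel spectral search.

    Parameters
    ----------
    band_low, band_high
        Physiological frequency band searched for a beat peak, in Hz.
        The default 2-20 Hz brackets the 7-10 Hz range typical of healthy
        differentiated cultures with margin; ``band_high`` must stay below
        the Nyquist frequency of the recording.
    snr_threshold
        A pixel is active when its in-band peak power is at least this
        multiple of the median in-band power.  The default of 15 holds the
        per-pixel false-positive rate on pure-noise traces near 1% for
        typical recordings (a few hundred in-band bins).
    detrend
        ``"mean"`` removes the temporal mean; ``"linear"`` removes a
        least-squares line (slow photobleaching / focus drift).
    window
        Optional ``"hann"`` taper applied after detrending.
    """

    band_low: float = 2.0
    band_high: float = 20.0
    snr_threshold: float = 15.0
    detrend: str = "mean"
    window: str = "none"

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError(
                f"need 0 < band_low < band_high, got ({self.band_low}, {self.band_high})"
            )
        if self.snr_threshold <= 0:
            raise ValueError("snr_threshold must be positive")
        if self.detrend not in ("mean", "linear"):
            raise ValueError(f"detrend must be 'mean' or 'linear', got {self.detrend!r}")
        if self.window not in ("none", "hann"):
            raise ValueError(f"window must be 'none' or 'hann', got {self.window!r}")

    def validate_against_fps(self, fps: float) -> None:
        if fps <= 2 * self.band_high:
            raise ValueError(
                f"band_high={self.band_high} Hz violates Nyquist: frame rate {fps} fps "
                f"resolves frequencies only below {fps / 2} Hz"
            )


@dataclass(frozen=True)
class FrequencyMap:
    """Per-pixel dominant beat frequency; NaN marks inactive pixels."""

    values: np.ndarray  # (H, W) float, Hz; NaN = inactive
    fps: float
    config: SpectralConfig | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {values.shape}")
        object.__setattr__(self, "values", values)
        if self.config is not None:
            active = values[np.isfinite(values)]
            if active.size and (
                active.min() < self.config.band_low or active.max() > self.config.band_high
            ):
                raise ValueError("active frequencies fall outside the configured band")

    @property
    def active_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class CiliaSummary:
    """Area covered by active cilia and their mean beat frequency."""

    active_area_pct: float
    mean_cbf: float  # Hz; NaN when n_active == 0
    n_active: int
    n_analyzed: int


def _detrend(traces: np.ndarray, mode: str) -> np.ndarray:
    """Remove per-trace mean or least-squares line along axis 0."""
    if mode == "mean":
        return traces - traces.mean(axis=0, keepdims=True)
    # linear: project out [1, t]
    T = traces.shape[0]
    t = np.arange(T, dtype=float)
    t = t - t.mean()
    centered = traces - traces.mean(axis=0, keepdims=True)
    slope = (t @ centered.reshape(T, -1)).reshape((1,) + traces.shape[1:]) / (t @ t)
    return centered - slope * t.reshape((T,) + (1,) * (traces.ndim - 1))


def _power_spectrum(traces: np.ndarray, fps: float, config: SpectralConfig):
    """One-sided power spectrum along axis 0, zero-frequency bin dropped.

    Power below a numerical floor proportional to the squared trace
    magnitude is snapped to exactly zero, so constant or linearly drifting
    traces produce all-zero spectra instead of floating-point residue that
    a purely relative peak criterion could mistake for a signal.
    """
    traces = np.asarray(traces, dtype=float)
    T = traces.shape[0]
    x = _detrend(traces, config.detrend)
    if config.window == "hann":
        w = np.hanning(T).reshape((T,) + (1,) * (x.ndim - 1))
        x = x * w
    spec = np.fft.rfft(x, axis=0)
    power = np.abs(spec) ** 2
    scale = np.sqrt((traces**2).mean(axis=0, keepdims=True))
    floor = (T * scale * 1e-9) ** 2
    power = np.where(power > floor, power, 0.0)
    freqs = np.fft.rfftfreq(T, d=1.0 / fps)
    # the zero-frequency (DC) bin is excluded by contract
    return freqs[1:], power[1:]


def pixel_spectrum(trace: np.ndarray, fps: float, config: SpectralConfig | None = None):
    """One-sided power spectrum of a single pixel trace.

    Returns ``(frequencies, power)`` with the zero-frequency bin removed;
    the frequency resolution is ``fps / T``.  A constant trace yields an
    all-zero spectrum (the detrend step removes it entirely).
    """
    config = config or SpectralConfig()
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("trace must be one-dimensional")
    if trace.size < MIN_FRAMES:
        raise ValueError(f"trace must have at least {MIN_FRAMES} samples, got {trace.size}")
    return _power_spectrum(trace, fps, config)


def detect_meaningful_frequency(
    spectrum: tuple[np.ndarray, np.ndarray], config: SpectralConfig | None = None
) -> float | None:
    """Dominant in-band frequency of a spectrum, or ``None`` if inactive.

    The in-band power maximum is accepted (pixel active) iff it is at least
    ``snr_threshold`` times the median in-band power; the comparison is
    inclusive.  An all-zero spectrum is always inactive.
    """
    config = config or SpectralConfig()
    freqs, power = spectrum
    band = (freqs >= config.band_low) & (freqs <= config.band_high)
    if not band.any():
        return None
    f_band = freqs[band]
    p_band = power[band]
    i_peak = int(np.argmax(p_band))
    peak = p_band[i_peak]
    if peak <= 0:
        return None
    if peak >= config.snr_threshold * np.median(p_band):
        return float(f_band[i_peak])
    return None


def compute_frequency_map(stack: VideoStack, config: SpectralConfig | None = None) -> FrequencyMap:
    """Apply the spectral search independently to every pixel of a stack.

    Deterministic for fixed input; pixels are treated independently (no
    spatial smoothing).  Rejects configurations whose band reaches the
    Nyquist frequency of the recording.
    """
    config = config or SpectralConfig()
    config.validate_against_fps(stack.fps)
    T, H, W = stack.frames.shape
    freqs, power = _power_spectrum(stack.frames.reshape(T, H * W), stack.fps, config)
    band = (freqs >= config.band_low) & (freqs <= config.band_high)
    f_band = freqs[band]
    p_band = power[band]  # (n_bins, H*W)
    i_peak = np.argmax(p_band, axis=0)
    peak = p_band[i_peak, np.arange(H * W)]
    median = np.median(p_band, axis=0)
    active = (peak > 0) & (peak >= config.snr_threshold * median)
    values = np.where(active, f_band[i_peak], np.nan).reshape(H, W)
    return FrequencyMap(values=values, fps=stack.fps, config=config)


def summarize_cilia(fmap: FrequencyMap, roi_mask: np.ndarray | None = None) -> CiliaSummary:
    """Percent area covered by active cilia and mean CBF over active pixels.

    ``roi_mask`` restricts the analyzed pixels; when no pixel is active the
    mean CBF is reported as NaN rather than raising.
    """
    values = fmap.values
    if roi_mask is not None:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != values.shape:
            raise ValueError("roi_mask shape must match the frequency map")
        if not roi_mask.any():
            raise ValueError("roi_mask selects no pixels")
        values = values[roi_mask]
    n_analyzed = values.size
    active = values[np.isfinite(values)]
    n_active = active.size
    mean_cbf = float(active.mean()) if n_active else float("nan")
    return CiliaSummary(
        active_area_pct=100.0 * n_active / n_analyzed,
        mean_cbf=mean_cbf,
        n_active=n_active,
        n_analyzed=n_analyzed,
    )


def render_false_color(fmap: FrequencyMap, cmap: str = "hot"):
    """False-color rendering of a frequency map.

    Inactive pixels are black; active pixels are mapped linearly from
    ``[band_low, band_high]`` onto a temperature-style lookup table.
    Returns ``(rgb, meta)`` where ``rgb`` is an (H, W, 3) uint8 image and
    ``meta`` records the colorbar range and colormap name.
    """
    import matplotlib

    config = fmap.config or SpectralConfig()
    lut = matplotlib.colormaps[cmap]
    lo, hi = config.band_low, config.band_high
    values = fmap.values
    frac = np.clip((values - lo) / (hi - lo), 0.0, 1.0)
    active = np.isfinite(values)
    rgb = np.zeros(values.shape + (3,), dtype=np.uint8)
    if active.any():
        colors = lut(frac[active])[:, :3]
        rgb[active] = np.round(colors * 255).astype(np.uint8)
    meta = {"band_low": lo, "band_high": hi, "cmap": cmap, "inactive_color": "black"}
    return rgb, meta
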