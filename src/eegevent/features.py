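"""Cepstral feature extraction for EEG channels.

Each montaged channel is converted into a sequence of 26-dimensional
feature vectors computed every 0.1 s from a 0.2 s overlapping analysis
window: seven linear-frequency cepstral coefficients (LFCCs, the
zeroth coefficient discarded), a frequency-domain log-energy term, a
differential energy term (max minus min of log-energy over a 0.9 s
window, which separates transient pulses from stationary background),
first derivatives of all nine absolute terms, and second derivatives of
eight of them (the differential-energy second derivative is excluded):
7 + 1 + 1 + 9 + 8 = 26.

LFCCs follow the classic filter-bank cepstrum recipe — Hamming taper,
high-resolution FFT, triangular filter bank linearly spaced in
frequency with 50% overlap, log compression, orthonormal DCT-II —
except that the filter bank is linear rather than mel-scaled, which
suits the low-frequency content of EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.fft import dct, rfft
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal.windows import hamming

from .edf_io import SignalRecord

LOG_FLOOR = 1e-10  # floor inside logs so silent frames stay finite


@dataclass(frozen=True)
class FeatureConfig:
    """Front-end parameters.

    Defaults give the canonical 26-dimensional vector at 250 Hz:
    0.1 s frame step, 0.2 s analysis window, 64-point FFT, 24
    triangular filters over 0-125 Hz, 7 cepstra, 0.9 s differential
    energy window, derivative regression windows of 9 and 3 frames.
    """

    frame_step: float = 0.1
    analysis_window: float = 0.2
    n_cepstra: int = 7
    n_filters: int = 24
    fft_size: int = 64
    diff_energy_window: float = 0.9
    delta_window: int = 9
    delta_delta_window: int = 3
    band: tuple[float, float] = (0.0, 125.0)
    energy_from_filterbank: bool = True

    def __post_init__(self) -> None:
        if self.frame_step > self.analysis_window:
            raise ValueError("frame_step must not exceed analysis_window")
        if self.n_cepstra >= self.n_filters:
            raise ValueError("n_cepstra must be < n_filters")
        ratio = self.diff_energy_window / self.frame_step
        if round(ratio) % 2 != 1 or abs(ratio - round(ratio)) > 1e-6:
            raise ValueError(
                "diff_energy_window must be an odd multiple of frame_step"
            )

    def step_samples(self, rate: float) -> int:
        return int(round(self.frame_step * rate))

    def window_samples(self, rate: float) -> int:
        n = int(round(self.analysis_window * rate))
        if self.fft_size < n:
            raise ValueError(
                f"fft_size {self.fft_size} < window of {n} samples"
            )
        return n

    @property
    def ed_frames(self) -> int:
        return int(round(self.diff_energy_window / self.frame_step))

    @property
    def n_absolute(self) -> int:
        return self.n_cepstra + 2  # cepstra + E_f + E_d

    @property
    def dimension(self) -> int:
        # absolute terms, their deltas, delta-deltas of all but E_d
        return 3 * self.n_absolute - 1


@dataclass
class FeatureSequence:
    """Per-channel frame matrix ``(n_frames, dimension)``."""

    frames: np.ndarray
    frame_step: float
    channel_index: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Framing and spectrum
# ---------------------------------------------------------------------------

def frame_signal(
    channel: np.ndarray, config: FeatureConfig, rate: float = 250.0
) -> np.ndarray:
    """Slice a channel into overlapping frames, one per frame step.

    Returns an array ``(n_frames, window_samples)`` where
    ``n_frames = floor(n_samples / step)``; the record tail is
    zero-padded so the final frame exists.
    """
    channel = np.asarray(channel, dtype=np.float64)
    step = config.step_samples(rate)
    win = config.window_samples(rate)
    if channel.size < win:
        raise ValueError(
            f"channel of {channel.size} samples is shorter than one "
            f"{win}-sample analysis window"
        )
    n_frames = channel.size // step
    padded = np.pad(channel, (0, max(0, (n_frames - 1) * step + win - channel.size)))
    idx = np.arange(win)[None, :] + step * np.arange(n_frames)[:, None]
    return padded[idx]


@lru_cache(maxsize=8)
def _taper(win: int) -> np.ndarray:
    return hamming(win, sym=False)


def frame_spectrum(frame: np.ndarray, config: FeatureConfig) -> np.ndarray:
    """Hamming-tapered power spectrum ``|X(k)|^2``, ``fft_size/2 + 1`` bins."""
    frame = np.atleast_2d(np.asarray(frame, dtype=np.float64))
    tapered = frame * _taper(frame.shape[-1])
    spec = np.abs(rfft(tapered, n=config.fft_size, axis=-1)) ** 2
    return spec[0] if spec.shape[0] == 1 else spec


@lru_cache(maxsize=8)
def _filterbank_matrix(
    n_filters: int, fft_size: int, rate: float, f_lo: float, f_hi: float
) -> np.ndarray:
    """Triangular filters linearly spaced over the band, 50% overlap."""
    n_bins = fft_size // 2 + 1
    freqs = np.arange(n_bins) * rate / fft_size
    edges = np.linspace(f_lo, f_hi, n_filters + 2)
    fb = np.zeros((n_filters, n_bins))
    for i in range(n_filters):
        lo, ctr, hi = edges[i], edges[i + 1], edges[i + 2]
        rising = (freqs - lo) / (ctr - lo)
        falling = (hi - freqs) / (hi - ctr)
        fb[i] = np.clip(np.minimum(rising, falling), 0.0, None)
    return fb


def _filterbank_outputs(spectrum: np.ndarray, config: FeatureConfig,
                        rate: float = 250.0) -> np.ndarray:
    fb = _filterbank_matrix(
        config.n_filters, config.fft_size, rate, *config.band
    )
    return np.asarray(spectrum) @ fb.T


def frequency_energy(
    spectrum: np.ndarray, config: FeatureConfig | None = None,
    rate: float = 250.0,
) -> np.ndarray | float:
    """Log energy ``E_f = log(sum of energies)``, floored to stay finite.

    By default the sum runs over the (oversampled) filter-bank outputs;
    with ``energy_from_filterbank=False`` it runs over the raw FFT
    bins.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if config is not None and config.energy_from_filterbank:
        total = _filterbank_outputs(spectrum, config, rate).sum(axis=-1)
    else:
        total = spectrum.sum(axis=-1)
    return np.log(np.maximum(total, LOG_FLOOR))


def filterbank_cepstra(
    spectrum: np.ndarray, config: FeatureConfig, rate: float = 250.0
) -> np.ndarray:
    """Cepstra ``c_1..c_n`` via log filter bank + orthonormal DCT-II.

    The zeroth coefficient (overall log level) is discarded; the
    frequency-energy term replaces it.
    """
    fb_out = _filterbank_outputs(spectrum, config, rate)
    log_fb = np.log(np.maximum(fb_out, LOG_FLOOR))
    ceps = dct(log_fb, type=2, norm="ortho", axis=-1)
    return ceps[..., 1 : config.n_cepstra + 1]


# ---------------------------------------------------------------------------
# Energy dynamics and derivatives
# ---------------------------------------------------------------------------

def differential_energy(
    ef: np.ndarray, config: FeatureConfig
) -> np.ndarray:
    """``E_d(t) = max - min`` of ``E_f`` over a centered window.

    The window (0.9 s = 9 frames by default) is clipped to the valid
    frame range at the record edges; replicated-edge filtering is
    equivalent since duplicates change neither max nor min.
    """
    ef = np.asarray(ef, dtype=np.float64)
    size = config.ed_frames
    hi = maximum_filter1d(ef, size=size, mode="nearest")
    lo = minimum_filter1d(ef, size=size, mode="nearest")
    return hi - lo


def regression_deltas(series: np.ndarray, n_half: int) -> np.ndarray:
    """Regression derivative ``d_t = sum_n n (c_{t+n} - c_{t-n}) / (2 sum n^2)``.

    Boundary values are replicated so the output has the input length.
    ``series`` may be 1-D ``(T,)`` or 2-D ``(T, dims)``.
    """
    if n_half < 1:
        raise ValueError("regression half-window must be >= 1")
    series = np.asarray(series, dtype=np.float64)
    squeeze = series.ndim == 1
    x = series[:, None] if squeeze else series
    padded = np.pad(x, ((n_half, n_half), (0, 0)), mode="edge")
    t0 = n_half
    num = np.zeros_like(x)
    for n in range(1, n_half + 1):
        num += n * (padded[t0 + n : t0 + n + x.shape[0]]
                    - padded[t0 - n : t0 - n + x.shape[0]])
    denom = 2.0 * sum(n * n for n in range(1, n_half + 1))
    d = num / denom
    return d[:, 0] if squeeze else d


# ---------------------------------------------------------------------------
# Full front end
# ---------------------------------------------------------------------------

def channel_features(
    channel: np.ndarray, config: FeatureConfig, rate: float = 250.0
) -> np.ndarray:
    """26-dim feature matrix ``(n_frames, dimension)`` for one channel.

    Layout per frame: ``[c1..c7, E_f, E_d]`` then deltas of all nine,
    then delta-deltas of all but ``E_d``.
    """
    frames = frame_signal(channel, config, rate)
    spec = frame_spectrum(frames, config)
    ceps = filterbank_cepstra(spec, config, rate)
    ef = frequency_energy(spec, config, rate)
    ed = differential_energy(ef, config)
    absolute = np.column_stack([ceps, ef, ed])
    deltas = regression_deltas(absolute, config.delta_window)
    # second derivative excludes the differential-energy column (last)
    ddeltas = regression_deltas(deltas[:, :-1], config.delta_delta_window)
    return np.column_stack([absolute, deltas, ddeltas])


def extract_features(
    record: SignalRecord, config: FeatureConfig | None = None
) -> list[FeatureSequence]:
    """Feature sequences for every channel of a canonical 250 Hz record."""
    config = config or FeatureConfig()
    return [
        FeatureSequence(
            frames=channel_features(record.samples[ch], config, record.rate),
            frame_step=config.frame_step,
            channel_index=ch,
        )
        for ch in range(record.n_channels)
    ]
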