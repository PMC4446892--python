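"""Audio I/O, spectrograms, and narrowband pitch-contour extraction.

This module handles the raw-signal layer of the pipeline: reading mono WAV
recordings (birdsong at 44.1 kHz, mouse ultrasonic sessions at 250 kHz),
computing short-time spectra and spectral derivatives, and reducing a
narrowband ultrasonic call to a pitch contour — one pitch value (kHz) per
~0.88 ms of call, obtained by estimating a dominant frequency in 44-sample
windows and taking the median over every 5 consecutive windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

__all__ = [
    "AudioFormatError",
    "Waveform",
    "Spectrogram",
    "PitchContour",
    "read_wav",
    "write_wav",
    "spectrogram",
    "pitch_contour",
    "CONTOUR_WINDOW_SAMPLES",
    "CONTOUR_MEDIAN_BLOCK",
]

#: samples per elementary pitch window (non-overlapping)
CONTOUR_WINDOW_SAMPLES = 44
#: consecutive elementary windows aggregated by a median into one contour point
CONTOUR_MEDIAN_BLOCK = 5


class AudioFormatError(ValueError):
    """Raised when a WAV file cannot be interpreted as mono audio."""


@dataclass
class Waveform:
    """Mono audio signal with samples scaled to [-1, 1]."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise AudioFormatError(
                f"expected mono signal, got shape {self.samples.shape}"
            )
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return len(self.samples) / self.rate

    def slice_seconds(self, start: float, stop: float) -> "Waveform":
        """Half-open slice [start, stop) in seconds (sample-rounded)."""
        i = int(round(start * self.rate))
        j = int(round(stop * self.rate))
        return Waveform(self.samples[i:j], self.rate)


@dataclass
class Spectrogram:
    """Short-time magnitude (or spectral-derivative) matrix, time x frequency."""

    magnitudes: np.ndarray
    window_length: float
    step: float
    freq_axis: np.ndarray
    derivative: bool = False


@dataclass
class PitchContour:
    """Pitch (kHz) per aggregated window of a narrowband call.

    ``window_seconds`` is the duration covered by one contour value
    (44 * 5 / rate; ~0.88 ms at 250 kHz).
    """

    pitches: np.ndarray
    window_seconds: float
    band_low: float = 40.0
    band_high: float = 120.0

    def __post_init__(self) -> None:
        self.pitches = np.asarray(self.pitches, dtype=np.float64)
        if not self.band_low < self.band_high:
            raise ValueError("band_low must be < band_high")

    def __len__(self) -> int:
        return len(self.pitches)

    @property
    def duration(self) -> float:
        return len(self.pitches) * self.window_seconds


def read_wav(path: str | Path) -> Waveform:
    """Read a mono PCM or float WAV file, scaling samples to [-1, 1].

    Integer PCM is scaled by the full-scale magnitude of its dtype
    (e.g. int16 sample 32767 -> 32767/32768).
    """
    path = Path(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # chunk warnings from odd encoders
            rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # wavfile raises bare ValueError on bad headers
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.ndim != 1:
        raise AudioFormatError(
            f"{path}: expected mono audio, got {data.shape[1]} channels"
        )
    if data.size == 0:
        raise AudioFormatError(f"{path}: empty audio stream")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise AudioFormatError(f"{path}: unsupported sample format {data.dtype}")
    return Waveform(samples, float(rate))


def write_wav(path: str | Path, w: Waveform, bit_depth: int = 16) -> None:
    """Write a waveform as PCM WAV (16-bit) or float32 (bit_depth=32)."""
    path = Path(path)
    if bit_depth == 16:
        clipped = np.clip(w.samples, -1.0, 32767.0 / 32768.0)
        data = np.round(clipped * 32768.0).astype(np.int16)
    elif bit_depth == 32:
        data = w.samples.astype(np.float32)
    else:
        raise ValueError("bit_depth must be 16 (PCM) or 32 (float)")
    wavfile.write(path, int(round(w.rate)), data)


def _frame(samples: np.ndarray, n_window: int, n_step: int) -> np.ndarray:
    """Frame a signal into overlapping windows: (n_frames, n_window)."""
    n_frames = (len(samples) - n_window) // n_step + 1
    if n_frames < 1:
        raise ValueError(
            f"signal of {len(samples)} samples shorter than one "
            f"{n_window}-sample window"
        )
    view = np.lib.stride_tricks.sliding_window_view(samples, n_window)
    return view[:: n_step][:n_frames]


def spectrogram(
    w: Waveform,
    window_length: float,
    step: float,
    derivative: bool = False,
) -> Spectrogram:
    """Short-time magnitude spectrogram (Hann window), optionally as a
    spectral derivative.

    The derivative form is the first difference of log magnitude along time
    (the first frame is zeroed so the matrix keeps one row per window); it is
    near zero wherever the signal is stationary.
    """
    if not (window_length >= step > 0):
        raise ValueError("require window_length >= step > 0")
    n_window = int(round(window_length * w.rate))
    n_step = int(round(step * w.rate))
    frames = _frame(w.samples, n_window, n_step)
    win = np.hanning(n_window)
    mags = np.abs(np.fft.rfft(frames * win, axis=1))
    freq_axis = np.fft.rfftfreq(n_window, d=1.0 / w.rate)
    if derivative:
        logmag = np.log(mags + 1e-12)
        d = np.diff(logmag, axis=0, prepend=logmag[:1])
        mags = d
    return Spectrogram(mags, window_length, step, freq_axis, derivative)


def pitch_contour(
    w: Waveform,
    band_low: float = 40.0,
    band_high: float = 120.0,
    estimator: str = "weighted_mean",
) -> PitchContour:
    """Extract the pitch contour of a narrowband call.

    The call is cut into non-overlapping 44-sample windows; in each window a
    dominant frequency is estimated from the spectrum restricted to
    [band_low, band_high] kHz (spectral masking); the median over every 5
    consecutive windows gives one contour value (~0.88 ms at 250 kHz).
    Trailing samples/windows not filling a full block are dropped.

    Parameters
    ----------
    estimator:
        ``"weighted_mean"`` — power-weighted mean frequency of the masked
        spectrum (default, robust for narrowband calls);
        ``"peak"`` — frequency of the strongest masked bin.
    """
    nw, nb = CONTOUR_WINDOW_SAMPLES, CONTOUR_MEDIAN_BLOCK
    if len(w) < nw * nb:
        raise ValueError(
            f"call of {len(w)} samples too short for a pitch contour "
            f"(need at least {nw * nb})"
        )
    if estimator not in ("weighted_mean", "peak"):
        raise ValueError(f"unknown pitch estimator {estimator!r}")
    n_win = len(w) // nw
    frames = w.samples[: n_win * nw].reshape(n_win, nw)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    freqs_khz = np.fft.rfftfreq(nw, d=1.0 / w.rate) / 1000.0
    mask = (freqs_khz >= band_low) & (freqs_khz <= band_high)
    if not mask.any():
        raise ValueError(
            f"band [{band_low}, {band_high}] kHz contains no spectral bin at "
            f"rate {w.rate} Hz"
        )
    bandpower = power[:, mask]
    bandfreqs = freqs_khz[mask]
    if estimator == "peak":
        pitches = bandfreqs[np.argmax(bandpower, axis=1)]
    else:
        total = bandpower.sum(axis=1)
        # silent windows fall back to band midpoint (no energy to weight)
        safe = np.where(total > 0, total, 1.0)
        pitches = np.where(
            total > 0,
            bandpower @ bandfreqs / safe,
            0.5 * (band_low + band_high),
        )
    n_blocks = n_win // nb
    blocks = pitches[: n_blocks * nb].reshape(n_blocks, nb)
    contour = np.median(blocks, axis=1)
    return PitchContour(
        contour,
        window_seconds=nw * nb / w.rate,
        band_low=band_low,
        band_high=band_high,
    )


def export_spectrogram_csv(spec: Spectrogram, path: str | Path) -> None:
    """Dump a spectrogram as delimited text (rows = windows) for debugging."""
    header = ",".join(f"{f:.1f}" for f in spec.freq_axis)
    np.savetxt(path, spec.magnitudes, delimiter=",", header=header, comments="")
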