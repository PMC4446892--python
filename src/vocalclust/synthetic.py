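"""Ground-truthed synthetic vocal sessions.

Generates frequency-modulated tone calls following the canonical ultrasonic
archetype shapes (flat, upsweep, downsweep, chevron, complex), sequences
them with a known first-order Markov chain, places them with configurable
inter-call gaps, and adds white Gaussian noise — so every pipeline stage
(segmentation, similarity, clustering, assignment, syntax) can be scored
against known ground truth. Birdsong-like broadband fixtures reuse the same
machinery at 44.1 kHz with a harmonic stack (3 partials), giving the
feature backend non-trivial entropy and pitch-goodness structure.

The noise model is additive white Gaussian: enough to exercise detection
thresholds, with no claim of acoustic realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .signal_io import Waveform

__all__ = [
    "ArchetypeSpec",
    "SessionSpec",
    "synth_call",
    "synth_session",
    "default_archetypes",
    "novel_archetypes",
]

SHAPES = ("flat", "upsweep", "downsweep", "chevron", "complex")


@dataclass
class ArchetypeSpec:
    """One call archetype: a contour shape plus rendition jitter."""

    name: str
    shape: str = "flat"
    f_start: float = 70.0  # kHz
    f_end: float = 70.0
    f_peak: float = 90.0  # chevron apex / complex modulation center
    duration: float = 0.040  # seconds
    amplitude: float = 0.5
    freq_jitter: float = 1.0  # per-rendition frequency offset SD (kHz)
    duration_jitter: float = 0.05  # per-rendition duration SD (fraction)
    harmonics: int = 1  # partials (use 3 for birdsong-like fixtures)

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; one of {SHAPES}")
        if self.duration <= 0 or not 0 < self.amplitude <= 1:
            raise ValueError("duration must be positive and amplitude in (0, 1]")


@dataclass
class SessionSpec:
    """A synthetic recording session: archetypes + Markov syntax + placement."""

    archetypes: list[ArchetypeSpec]
    markov: np.ndarray | None = None  # defaults to uniform transitions
    n_calls: int = 50
    gap_mean: float = 0.100  # seconds between call offset and next onset
    gap_sd: float = 0.020
    noise_sd: float = 0.002  # additive white noise (amplitude units)
    rate: float = 250_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.archetypes)
        if k == 0:
            raise ValueError("need at least one archetype")
        if self.markov is None:
            self.markov = np.full((k, k), 1.0 / k)
        self.markov = np.asarray(self.markov, dtype=float)
        if self.markov.shape != (k, k) or not np.allclose(self.markov.sum(axis=1), 1.0):
            raise ValueError("markov must be k x k with rows summing to 1")


def default_archetypes(k: int = 4) -> list[ArchetypeSpec]:
    """Canonical well-separated ultrasonic archetype sets (k in 3..5).

    A flat 70 kHz call, a 50->100 kHz upsweep, a 100->50 kHz downsweep, a
    60->110->60 kHz chevron, and a high-band trill (complex modulation in
    90-120 kHz) — shapes and band placements typical of mouse pup
    retrieval-call categories.
    """
    archetypes = [
        ArchetypeSpec(name="flat70", shape="flat", f_start=70.0, f_end=70.0),
        ArchetypeSpec(name="upsweep", shape="upsweep", f_start=50.0, f_end=100.0),
        ArchetypeSpec(name="downsweep", shape="downsweep", f_start=100.0, f_end=50.0),
        ArchetypeSpec(
            name="chevron", shape="chevron", f_start=60.0, f_peak=110.0, f_end=60.0
        ),
        ArchetypeSpec(name="trill", shape="complex", f_start=90.0, f_peak=105.0),
    ]
    if not 3 <= k <= len(archetypes):
        raise ValueError(f"k must be in 3..{len(archetypes)}")
    return archetypes[:k]


def novel_archetypes() -> list[ArchetypeSpec]:
    """Out-of-repertoire archetypes relative to ``default_archetypes(3)``."""
    return default_archetypes(5)[3:]


def _contour(a: ArchetypeSpec, t: np.ndarray) -> np.ndarray:
    """Instantaneous frequency (kHz) along normalized time t in [0, 1]."""
    if a.shape == "flat":
        return np.full_like(t, a.f_start)
    if a.shape == "upsweep" or a.shape == "downsweep":
        return a.f_start + (a.f_end - a.f_start) * t
    if a.shape == "chevron":
        up = a.f_start + (a.f_peak - a.f_start) * (t * 2)
        down = a.f_peak + (a.f_end - a.f_peak) * (t * 2 - 1)
        return np.where(t < 0.5, up, down)
    # complex: sinusoidal modulation around f_peak
    depth = max(abs(a.f_peak - a.f_start), 5.0)
    return a.f_peak + depth * np.sin(2 * np.pi * 3.0 * t)


def synth_call(
    a: ArchetypeSpec,
    rate: float = 250_000.0,
    seed: int | None = None,
    freq_offset: float = 0.0,
    duration_scale: float = 1.0,
) -> Waveform:
    """Synthesize one rendition of an archetype.

    The call is a frequency-modulated tone following the archetype contour
    (phase-integrated, so the instantaneous frequency is exact), with
    ``harmonics`` partials of decaying amplitude and 1 ms cosine on/off
    ramps. ``freq_offset``/``duration_scale`` apply rendition jitter.
    """
    duration = a.duration * duration_scale
    n = max(int(round(duration * rate)), 8)
    t = np.arange(n) / (n - 1)
    f_khz = _contour(a, t) + freq_offset
    f_hz = f_khz * 1000.0
    if (f_hz * a.harmonics).max() >= rate / 2:
        raise ValueError(
            f"archetype {a.name!r}: frequency {f_hz.max():.0f} Hz x "
            f"{a.harmonics} harmonics exceeds Nyquist at rate {rate:.0f} Hz"
        )
    phase = 2 * np.pi * np.cumsum(f_hz) / rate
    samples = np.zeros(n)
    for h in range(1, a.harmonics + 1):
        samples += a.amplitude / (2.0 ** (h - 1)) * np.sin(h * phase)
    ramp = min(int(0.001 * rate), n // 4)
    if ramp > 0:
        env = np.ones(n)
        ramp_curve = 0.5 * (1 - np.cos(np.pi * np.arange(ramp) / ramp))
        env[:ramp] = ramp_curve
        env[-ramp:] = ramp_curve[::-1]
        samples *= env
    return Waveform(samples, rate)


def synth_session(s: SessionSpec) -> tuple[Waveform, pd.DataFrame]:
    """Generate a full session: waveform plus ground-truth element table.

    Calls are sequenced by the Markov chain (uniform initial state), placed
    with Gaussian-sampled inter-call gaps (non-positive draws are
    resampled), and the whole track gets additive white noise. The returned
    table has one row per emitted call: element_id, seq_index, archetype,
    onset_s, duration_s.
    """
    rng = np.random.default_rng(s.seed)
    k = len(s.archetypes)
    states = [int(rng.integers(k))]
    for _ in range(s.n_calls - 1):
        states.append(int(rng.choice(k, p=s.markov[states[-1]])))

    calls, truth = [], []
    cursor = s.gap_mean  # lead-in silence
    for seq, state in enumerate(states):
        a = s.archetypes[state]
        offset = rng.normal(0.0, a.freq_jitter)
        dscale = max(0.2, 1.0 + rng.normal(0.0, a.duration_jitter))
        call = synth_call(a, rate=s.rate, freq_offset=offset, duration_scale=dscale)
        calls.append((cursor, call))
        truth.append(
            {
                "element_id": f"truth_{seq:04d}",
                "seq_index": seq,
                "archetype": a.name,
                "onset_s": cursor,
                "duration_s": call.duration,
            }
        )
        gap = rng.normal(s.gap_mean, s.gap_sd)
        while gap <= 0:
            gap = rng.normal(s.gap_mean, s.gap_sd)
        cursor += call.duration + gap

    total = int(round((cursor + s.gap_mean) * s.rate))
    samples = rng.normal(0.0, s.noise_sd, size=total) if s.noise_sd > 0 else np.zeros(total)
    for onset, call in calls:
        i = int(round(onset * s.rate))
        samples[i : i + len(call)] += call.samples
    return Waveform(samples, s.rate), pd.DataFrame(truth)
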