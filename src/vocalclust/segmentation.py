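"""Extraction of discrete vocal elements from recordings.

Two regimes:

* ultrasonic sessions — amplitude-threshold detection: a call is a maximal
  supra-threshold region of the RMS envelope whose internal sub-threshold
  gaps are each shorter than 10 ms; a sound must exceed threshold for more
  than 2 ms to count, and anything longer than 150 ms is discarded as noise;
* pre-segmented birdsong — onset/duration tables exported by an external
  segmenter are used to clip each syllable from the raw recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .signal_io import Waveform, write_wav

__all__ = [
    "VocalElement",
    "SegmentationParams",
    "amplitude_envelope",
    "default_threshold",
    "segment_usv",
    "clip_from_table",
    "read_syllable_table",
    "segmentation_manifest",
    "export_elements",
]

#: RMS envelope window (seconds); kept below the 2 ms minimum-call rule so
#: smoothing cannot mask it
ENVELOPE_WINDOW = 0.001


@dataclass
class VocalElement:
    """One segmented syllable or call."""

    element_id: str
    session_id: str
    seq_index: int
    onset: float
    duration: float
    audio: Waveform

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"{self.element_id}: duration must be positive")


@dataclass
class SegmentationParams:
    """Amplitude-threshold segmentation parameters (seconds / envelope units).

    ``amp_threshold=None`` uses 5x the median envelope of the recording (a
    robust noise-floor multiple); the threshold is otherwise user-defined.
    """

    amp_threshold: float | None = None
    min_above: float = 0.002
    gap_close: float = 0.010
    max_duration: float = 0.150

    def __post_init__(self) -> None:
        if self.min_above <= 0 or self.gap_close <= 0 or self.max_duration <= 0:
            raise ValueError("segmentation durations must be positive")
        if self.min_above >= self.max_duration:
            raise ValueError("min_above must be < max_duration")


def amplitude_envelope(w: Waveform, window: float = ENVELOPE_WINDOW) -> np.ndarray:
    """RMS amplitude envelope over a centered sliding window."""
    n = max(int(round(window * w.rate)), 1)
    mean_sq = uniform_filter1d(w.samples**2, size=n, mode="nearest")
    return np.sqrt(np.maximum(mean_sq, 0.0))


def default_threshold(envelope: np.ndarray, multiple: float = 5.0) -> float:
    """Noise-floor threshold: ``multiple`` times the median envelope."""
    return multiple * float(np.median(envelope))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) sample indices."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        stops = np.r_[stops, len(mask)]
    return list(zip(starts.tolist(), stops.tolist()))


def segment_usv(
    w: Waveform,
    p: SegmentationParams | None = None,
    session_id: str = "session",
) -> list[VocalElement]:
    """Detect ultrasonic calls by amplitude thresholding.

    Supra-threshold envelope runs separated by sub-threshold gaps shorter
    than ``gap_close`` are grouped into one call (the call ends at the last
    supra-threshold sample — the completion gap itself is not clipped).
    Groups whose longest contiguous supra-threshold run is shorter than
    ``min_above`` are rejected; groups longer than ``max_duration`` after gap
    closure are discarded whole as noise.
    """
    p = p or SegmentationParams()
    env = amplitude_envelope(w)
    thr = p.amp_threshold if p.amp_threshold is not None else default_threshold(env)
    runs = _runs(env >= thr)
    if not runs:
        return []
    gap = p.gap_close * w.rate
    # gap closure: merge runs whose separating silence is < gap_close
    groups: list[list[tuple[int, int]]] = [[runs[0]]]
    for r in runs[1:]:
        if r[0] - groups[-1][-1][1] < gap:
            groups[-1].append(r)
        else:
            groups.append([r])
    elements: list[VocalElement] = []
    seq = 0
    for g in groups:
        start, stop = g[0][0], g[-1][1]
        longest = max(b - a for a, b in g)
        if longest / w.rate < p.min_above:
            continue
        duration = (stop - start) / w.rate
        if duration > p.max_duration:
            continue  # merged noise is discarded whole
        elements.append(
            VocalElement(
                element_id=f"{session_id}_{seq:04d}",
                session_id=session_id,
                seq_index=seq,
                onset=start / w.rate,
                duration=duration,
                audio=Waveform(w.samples[start:stop].copy(), w.rate),
            )
        )
        seq += 1
    return elements


def read_syllable_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited syllable table (columns element_id, onset_s, duration_s)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    table = pd.read_csv(path, sep=sep)
    missing = {"element_id", "onset_s", "duration_s"} - set(table.columns)
    if missing:
        raise ValueError(f"{path}: syllable table missing columns {sorted(missing)}")
    return table


def clip_from_table(
    w: Waveform,
    table: pd.DataFrame | str | Path,
    session_id: str = "session",
) -> list[VocalElement]:
    """Clip syllables from a recording using an onset/duration table.

    Each element is the exact sample slice
    [round(onset*rate), round((onset+duration)*rate)). Overlapping rows are
    all emitted; output is ordered by onset.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_syllable_table(table)
    rows = table.sort_values("onset_s", kind="stable").reset_index(drop=True)
    elements = []
    for seq, row in rows.iterrows():
        onset, duration = float(row["onset_s"]), float(row["duration_s"])
        i = int(round(onset * w.rate))
        j = int(round((onset + duration) * w.rate))
        if i < 0 or j > len(w) or j <= i:
            raise ValueError(
                f"syllable table row {row['element_id']!r}: interval "
                f"[{onset}, {onset + duration}] s outside recording of "
                f"{w.duration:.3f} s"
            )
        elements.append(
            VocalElement(
                element_id=str(row["element_id"]),
                session_id=session_id,
                seq_index=int(seq),
                onset=onset,
                duration=duration,
                audio=Waveform(w.samples[i:j].copy(), w.rate),
            )
        )
    return elements


def segmentation_manifest(
    elements: list[VocalElement],
    band_low: float = 40.0,
    band_high: float = 120.0,
) -> pd.DataFrame:
    """Review manifest (one row per element, with peak in-band energy).

    Stands in for the interactive noise-review step: the user can sort by
    ``peak_band_energy`` and drop rows before downstream stages.
    """
    records = []
    for e in elements:
        spec = np.abs(np.fft.rfft(e.audio.samples)) ** 2
        freqs = np.fft.rfftfreq(len(e.audio), d=1.0 / e.audio.rate) / 1000.0
        mask = (freqs >= band_low) & (freqs <= band_high)
        peak = float(spec[mask].max()) if mask.any() else 0.0
        records.append(
            {
                "element_id": e.element_id,
                "session_id": e.session_id,
                "seq_index": e.seq_index,
                "onset_s": e.onset,
                "duration_s": e.duration,
                "peak_band_energy": peak,
            }
        )
    return pd.DataFrame(records)


def export_elements(elements: list[VocalElement], out_dir: str | Path) -> list[Path]:
    """Write one WAV per element (mirrors the per-call clip workflow)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for e in elements:
        path = out_dir / f"{e.element_id}.wav"
        write_wav(path, e.audio)
        paths.append(path)
    return paths
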