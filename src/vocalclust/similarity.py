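"""Pairwise acoustic similarity scoring.

Two backends produce the all-pairs matrices consumed by clustering:

* ``finch_gs`` — broadband syllables are summarized millisecond-by-
  millisecond by four features (Wiener entropy, power-weighted mean
  frequency, frequency modulation, pitch goodness) in 9.3 ms windows with
  1 ms steps; pairs are compared in that feature space and summarized by a
  global similarity (GS) score = similarity x accuracy x temporal overlap
  / 10,000, on a 0-100 scale.
* ``mouse_contour`` — narrowband ultrasonic calls are reduced to pitch
  contours; a pair score is the product of the Pearson correlation of
  overlapping contour windows, a scaled pitch-difference term
  (1 - mean |dp| / 80 kHz for the 40-120 kHz band), and temporal overlap,
  on a -1..1 scale.

The broadband comparator follows the same output contract as the classic
similarity-batch tools (two percent-scaled terms plus temporal overlap and
the GS formula); it is calibrated so self-comparison scores 100 and
unrelated white-noise pairs average below 20 GS. Bit compatibility with any
external scorer is not claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .segmentation import VocalElement
from .signal_io import PitchContour, Waveform, pitch_contour

__all__ = [
    "FeatureTrajectory",
    "PairScore",
    "ContourPairScore",
    "SimilarityMatrix",
    "feature_trajectory",
    "score_pair_finch",
    "score_pair_usv",
    "build_similarity_matrix",
    "to_dissimilarity",
    "global_similarity",
    "FLAT_CONTOUR_TOL",
]

#: feature window and step of the broadband trajectory (seconds)
FEATURE_WINDOW = 0.0093
FEATURE_STEP = 0.001

#: contours with pitch SD below this (kHz) are treated as flat calls when
#: computing the degenerate Pearson correlation; set above the per-window
#: wiggle of the pitch estimator (~1 kHz at moderate SNR) and well below the
#: contour SD of genuinely modulated calls (>= ~3 kHz)
FLAT_CONTOUR_TOL = 2.0

# comparator calibration (pooled-SD units): a trajectory step "matches" the
# aligned step of the other syllable when their feature-space RMS distance is
# below _MATCH_DIST; accuracy decays linearly, reaching 0 at _ACC_SCALE
_MATCH_DIST = 0.75
_ACC_SCALE = 2.0
_MAX_SHIFT = 10  # alignment search, in 1-ms steps


@dataclass
class FeatureTrajectory:
    """Per-millisecond acoustic features of a broadband syllable."""

    entropy: np.ndarray
    mean_freq: np.ndarray
    fm: np.ndarray
    pitch_goodness: np.ndarray
    window: float = FEATURE_WINDOW
    step: float = FEATURE_STEP
    duration: float | None = None  # source-element duration (seconds)

    def __post_init__(self) -> None:
        lengths = {
            len(self.entropy),
            len(self.mean_freq),
            len(self.fm),
            len(self.pitch_goodness),
        }
        if len(lengths) != 1:
            raise ValueError("feature sequences must have equal length")

    def __len__(self) -> int:
        return len(self.entropy)

    def as_matrix(self) -> np.ndarray:
        """Steps x 4 feature matrix (entropy, mean_freq, fm, pitch_goodness)."""
        return np.column_stack(
            [self.entropy, self.mean_freq, self.fm, self.pitch_goodness]
        )


@dataclass
class PairScore:
    """Broadband pair score; ``gs = similarity*accuracy*temporal_overlap/10000``."""

    similarity: float
    accuracy: float
    temporal_overlap: float
    gs: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gs is None:
            self.gs = global_similarity(
                self.similarity, self.accuracy, self.temporal_overlap
            )


@dataclass
class ContourPairScore:
    """Ultrasonic pair score; ``score`` is the three-factor product in [-1, 1]."""

    pitch_corr: float
    pitch_diff_score: float
    temporal_overlap: float
    score: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.score is None:
            self.score = (
                self.pitch_corr * self.pitch_diff_score * self.temporal_overlap
            )


def global_similarity(similarity: float, accuracy: float, temporal_overlap: float) -> float:
    """GS on a 0-100 scale: similarity x accuracy x temporal overlap / 10,000."""
    return similarity * accuracy * temporal_overlap / 10000.0


def feature_trajectory(e: VocalElement | Waveform) -> FeatureTrajectory:
    """Compute the four-feature trajectory of a broadband syllable.

    Per 9.3 ms Hann window (1 ms steps): Wiener entropy = log of geometric
    over arithmetic mean of the power spectrum (0 for white noise, strongly
    negative for tones); power-weighted mean frequency; FM = angle (degrees)
    of spectral change over time vs over frequency; pitch goodness = peak of
    the real cepstrum in the 300 Hz - 8 kHz pitch range.
    """
    w = e.audio if isinstance(e, VocalElement) else e
    n_window = int(round(FEATURE_WINDOW * w.rate))
    n_step = int(round(FEATURE_STEP * w.rate))
    if len(w) < n_window:
        raise ValueError(
            f"element of {len(w)} samples shorter than one feature window "
            f"({n_window} samples)"
        )
    n_frames = (len(w) - n_window) // n_step + 1
    view = np.lib.stride_tricks.sliding_window_view(w.samples, n_window)
    frames = view[::n_step][:n_frames] * np.hanning(n_window)
    power = np.abs(np.fft.rfft(frames, axis=1)) ** 2
    power = power + 1e-30
    freqs = np.fft.rfftfreq(n_window, d=1.0 / w.rate)

    entropy = np.mean(np.log(power), axis=1) - np.log(np.mean(power, axis=1))
    mean_freq = power @ freqs / power.sum(axis=1)

    logp = np.log(power)
    d_time = np.diff(logp, axis=0, prepend=logp[:1])
    d_freq = np.diff(logp, axis=1, prepend=logp[:, :1])
    fm = np.degrees(
        np.arctan2(
            np.sqrt(np.mean(d_time**2, axis=1)),
            np.sqrt(np.mean(d_freq**2, axis=1)) + 1e-12,
        )
    )

    cep = np.fft.irfft(logp, axis=1)
    q_lo = max(int(w.rate / 8000.0), 1)
    q_hi = min(int(w.rate / 300.0), cep.shape[1] - 1)
    if q_hi <= q_lo:
        q_lo, q_hi = 1, cep.shape[1] - 1
    pitch_goodness = cep[:, q_lo:q_hi].max(axis=1)

    return FeatureTrajectory(
        entropy, mean_freq, fm, pitch_goodness, duration=len(w) / w.rate
    )


def _directed_match(
    fa: np.ndarray, fb: np.ndarray, scales: np.ndarray
) -> tuple[float, float]:
    """Best-alignment match of trajectory a against b.

    Returns (fraction of a's steps matched below threshold, mean normalized
    distance over the overlap at the best alignment).
    """
    la, lb = len(fa), len(fb)
    max_shift = min(_MAX_SHIFT, la - 1, lb - 1)
    best = (-1.0, np.inf)  # (n matched, mean distance); maximize then minimize
    for shift in range(-max_shift, max_shift + 1):
        a_lo, a_hi = max(0, -shift), min(la, lb - shift)
        if a_hi <= a_lo:
            continue
        da = fa[a_lo:a_hi]
        db = fb[a_lo + shift : a_hi + shift]
        dist = np.sqrt(np.mean(((da - db) / scales) ** 2, axis=1))
        n_match = float(np.count_nonzero(dist < _MATCH_DIST))
        mean_dist = float(dist.mean())
        if n_match > best[0] or (n_match == best[0] and mean_dist < best[1]):
            best = (n_match, mean_dist)
    frac = best[0] / la
    return frac, best[1]


def score_pair_finch(a: FeatureTrajectory, b: FeatureTrajectory) -> PairScore:
    """Score two broadband syllables in feature space.

    similarity = percent of steps whose feature-space distance to the best
    globally-aligned region of the other syllable is below a calibrated
    threshold; accuracy = 100*(1 - mean normalized distance / 2) over the
    matched overlap; temporal overlap = 100*min/max duration. The score is
    symmetrized by averaging the two comparison directions.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("feature trajectories must be non-empty")
    fa, fb = a.as_matrix(), b.as_matrix()
    pooled = np.vstack([fa, fb])
    scales = pooled.std(axis=0)
    scales[scales == 0] = 1.0
    frac_ab, dist_ab = _directed_match(fa, fb, scales)
    frac_ba, dist_ba = _directed_match(fb, fa, scales)
    similarity = 100.0 * 0.5 * (frac_ab + frac_ba)
    mean_dist = 0.5 * (dist_ab + dist_ba)
    accuracy = 100.0 * max(0.0, 1.0 - mean_dist / _ACC_SCALE)
    if a.duration is not None and b.duration is not None:
        dur_a, dur_b = a.duration, b.duration
    else:
        dur_a, dur_b = float(len(a)), float(len(b))
    temporal = 100.0 * min(dur_a, dur_b) / max(dur_a, dur_b)
    return PairScore(similarity, accuracy, temporal)


def score_pair_usv(a: PitchContour, b: PitchContour) -> ContourPairScore:
    """Score two ultrasonic calls by their pitch contours.

    Contours are onset-aligned; the overlap is the leading
    min(len_a, len_b)-window prefix. pitch_corr is the Pearson correlation
    over the overlap (two flat contours correlate 1, a flat against a
    modulated contour 0); pitch_diff_score = 1 - mean |dp| / band width;
    temporal overlap = min/max contour length.
    """
    n = min(len(a), len(b))
    if n < 2:
        raise ValueError("pitch contours must have length >= 2 for correlation")
    band = (min(a.band_low, b.band_low), max(a.band_high, b.band_high))
    pa, pb = a.pitches[:n], b.pitches[:n]
    flat_a = pa.std() < FLAT_CONTOUR_TOL
    flat_b = pb.std() < FLAT_CONTOUR_TOL
    if flat_a and flat_b:
        corr = 1.0
    elif flat_a or flat_b:
        corr = 0.0
    else:
        corr = float(np.corrcoef(pa, pb)[0, 1])
    diff_score = 1.0 - float(np.mean(np.abs(pa - pb))) / (band[1] - band[0])
    temporal = n / max(len(a), len(b))
    return ContourPairScore(corr, diff_score, temporal)


@dataclass
class SimilarityMatrix:
    """Symmetric all-pairs score matrix with backend-maximum diagonal."""

    values: np.ndarray
    element_ids: list[str]
    backend: str  # "finch_gs" | "mouse_contour"

    @property
    def backend_max(self) -> float:
        return 100.0 if self.backend == "finch_gs" else 1.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.element_ids, columns=self.element_ids)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="element_id")

    @classmethod
    def from_csv(cls, path, backend: str) -> "SimilarityMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns], backend)


def _to_contour(item, band_low: float, band_high: float) -> PitchContour:
    if isinstance(item, PitchContour):
        return item
    w = item.audio if isinstance(item, VocalElement) else item
    nyq_khz = w.rate / 2000.0
    if nyq_khz <= band_low:
        raise ValueError(
            f"sampling rate {w.rate} Hz leaves no spectrum in the "
            f"[{band_low}, {band_high}] kHz band"
        )
    if nyq_khz < band_high:
        warnings.warn(
            f"contour backend on a {w.rate/1000:.1f} kHz recording: band "
            f"clipped to [{band_low}, {nyq_khz:.1f}] kHz",
            stacklevel=3,
        )
        band_high = nyq_khz
    return pitch_contour(w, band_low=band_low, band_high=band_high)


def build_similarity_matrix(
    items: list,
    backend: str,
    element_ids: list[str] | None = None,
    band_low: float = 40.0,
    band_high: float = 120.0,
) -> SimilarityMatrix:
    """Score every pair of elements and assemble the M x M matrix.

    ``items`` may be :class:`VocalElement`s (features/contours are derived
    per backend) or ready-made :class:`FeatureTrajectory` /
    :class:`PitchContour` objects. The matrix is symmetric with the backend
    maximum (100 GS / score 1) on the diagonal.
    """
    if backend not in ("finch_gs", "mouse_contour"):
        raise ValueError(f"unknown backend {backend!r}")
    if len(items) < 2:
        raise ValueError("need at least 2 elements to build a similarity matrix")
    if element_ids is None:
        element_ids = [
            it.element_id if isinstance(it, VocalElement) else f"e{i:04d}"
            for i, it in enumerate(items)
        ]
    if backend == "mouse_contour":
        reps = [_to_contour(it, band_low, band_high) for it in items]
        score = lambda x, y: score_pair_usv(x, y).score  # noqa: E731
        diag = 1.0
    else:
        reps = [
            it if isinstance(it, FeatureTrajectory) else feature_trajectory(it)
            for it in items
        ]
        score = lambda x, y: score_pair_finch(x, y).gs  # noqa: E731
        diag = 100.0
    m = len(reps)
    values = np.full((m, m), diag, dtype=float)
    for i in range(m):
        for j in range(i + 1, m):
            s = score(reps[i], reps[j])
            values[i, j] = values[j, i] = s
    return SimilarityMatrix(values, list(element_ids), backend)


def to_dissimilarity(s: SimilarityMatrix) -> np.ndarray:
    """Dissimilarity matrix for hierarchical clustering.

    finch backend: Euclidean distances between rows of the GS matrix
    (profile distance); mouse backend: 1 - score, elementwise.
    """
    if s.backend == "finch_gs":
        d = squareform(pdist(s.values, metric="euclidean"))
    else:
        d = 1.0 - s.values
        np.fill_diagonal(d, 0.0)
        d = 0.5 * (d + d.T)
    return d
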