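"""Shared fixtures: synthetic sessions carried through the pipeline stages."""

from __future__ import annotations

import numpy as np
import pytest

from vocalclust.clustering import (
    ClusterSet,
    CutParams,
    cut_tree,
    hcluster,
    iterative_merge,
    select_plateau,
)
from vocalclust.segmentation import SegmentationParams, segment_usv
from vocalclust.signal_io import Waveform
from vocalclust.similarity import build_similarity_matrix, to_dissimilarity
from vocalclust.synthetic import SessionSpec, default_archetypes, synth_session


def make_tone(freq_hz: float, duration: float, rate: float, amp: float = 0.5) -> Waveform:
    t = np.arange(int(round(duration * rate))) / rate
    return Waveform(amp * np.sin(2 * np.pi * freq_hz * t), rate)


def cluster_session(archetypes, n_calls: int, seed: int):
    """Run synth -> segment -> score -> cluster -> merge; return all artifacts."""
    wave, truth = synth_session(
        SessionSpec(archetypes=archetypes, n_calls=n_calls, seed=seed)
    )
    elements = segment_usv(wave, SegmentationParams(), session_id=f"s{seed}")
    matrix = build_similarity_matrix(elements, "mouse_contour")
    d = to_dissimilarity(matrix)
    labels = cut_tree(hcluster(d), d, CutParams())
    trace = iterative_merge(
        labels, matrix.values, sim_values=matrix.values, backend_max=1.0
    )
    final, plateau = select_plateau(trace)
    cs = ClusterSet.build(
        matrix.element_ids, final, matrix.values,
        sim_values=matrix.values, backend_max=1.0,
    )
    return {
        "wave": wave,
        "truth": truth,
        "elements": elements,
        "matrix": matrix,
        "initial_labels": labels,
        "trace": trace,
        "plateau": plateau,
        "clusters": cs,
    }


@pytest.fixture(scope="session")
def usv_session_k3():
    """A 45-call session of 3 well-separated ultrasonic archetypes."""
    return cluster_session(default_archetypes(3), n_calls=45, seed=1)
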