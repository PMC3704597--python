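"""Recover the movement component living in a subspace as metric trajectories.

A trial's whitened row x' is projected onto a chosen orthonormal vector set
{e_k}; the projected component sum_k (x'.e_k) e_k is the part of the
(whitened) movement contained in that subspace.  De-whitening with the
trial's own subject statistics — multiply each variable by the subject SD and
add back the subject mean — returns metric marker trajectories, which can be
condition-averaged and exported as stick-figure frame tables with an optional
difference magnification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .basis import OrthonormalBasis, check_orthonormal
from .errors import StateError
from .layout import AssembledMatrix

__all__ = ["reconstruct", "condition_average", "export_frames", "PLANES"]

#: plane name -> 1-based (horizontal, vertical) axis pair; laboratory axis
#: conventions differ, so this is overridable in export_frames.
PLANES = {"sagittal": (1, 3), "frontal": (2, 3)}


def reconstruct(
    matrix: AssembledMatrix,
    vectors: np.ndarray | OrthonormalBasis | None,
) -> np.ndarray:
    """Movement component of each trial within span{vectors}, in metric units.

    Returns an array of shape ``(trials, markers, axes, timepoints)``.  With
    the full joint basis this reproduces the preprocessed trajectories; with
    an empty vector set it returns each subject's mean trajectory.
    """
    if not matrix.whitened or matrix.subject_stats is None:
        raise StateError("reconstruction needs a whitened matrix with subject stats")
    if isinstance(vectors, OrthonormalBasis):
        vectors = vectors.vectors
    V = (
        np.zeros((0, matrix.n_variables))
        if vectors is None or np.size(vectors) == 0
        else np.atleast_2d(np.asarray(vectors, dtype=float))
    )
    if len(V):
        check_orthonormal(V)
    stats = matrix.subject_stats
    comp = (matrix.values @ V.T) @ V if len(V) else np.zeros_like(matrix.values)
    out = np.empty_like(comp)
    for i, key in enumerate(matrix.row_meta):
        out[i] = comp[i] * stats.std[key.subject] + stats.mean[key.subject]
    lay = matrix.layout
    return out.reshape(matrix.n_trials, lay.markers, lay.axes, lay.timepoints)


def condition_average(
    reconstructions: np.ndarray, labels: np.ndarray
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-condition mean and per-time-point SD of reconstructed trajectories.

    ``reconstructions`` is the (trials, markers, axes, timepoints) output of
    :func:`reconstruct`; returns {condition: (mean, sd)} with arrays of shape
    (markers, axes, timepoints), ready for a two-condition overlay.
    """
    labels = np.asarray(labels)
    conds = list(dict.fromkeys(labels.tolist()))
    if len(conds) < 2:
        raise ValueError("need both conditions present")
    out = {}
    for c in conds:
        block = reconstructions[labels == c]
        ddof = 1 if block.shape[0] > 1 else 0
        out[str(c)] = (block.mean(axis=0), block.std(axis=0, ddof=ddof))
    return out


def export_frames(
    condition_means: dict[str, tuple[np.ndarray, np.ndarray] | np.ndarray],
    plane: str = "sagittal",
    magnification: float = 1.0,
    planes: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Stick-figure frame table of both conditions in a 2-D plane.

    Each condition's deviation from the two-condition grand mean is amplified
    by ``magnification`` (1 = true coordinates); columns are
    ``time_index`` (1-based), ``condition``, ``marker`` (1-based), ``coord1``
    (horizontal), ``coord2`` (vertical).
    """
    if magnification <= 0:
        raise ValueError("magnification must be > 0")
    planes = planes or PLANES
    if plane not in planes:
        raise ValueError(f"unknown plane {plane!r}; available: {sorted(planes)}")
    a1, a2 = (a - 1 for a in planes[plane])
    means = {
        c: (v[0] if isinstance(v, tuple) else np.asarray(v, float))
        for c, v in condition_means.items()
    }
    grand = np.mean(list(means.values()), axis=0)
    rows = []
    n_markers, _, n_time = grand.shape
    for c, mean in means.items():
        amplified = grand + magnification * (mean - grand)
        for t in range(n_time):
            for m in range(n_markers):
                rows.append(
                    (t + 1, c, m + 1, amplified[m, a1, t], amplified[m, a2, t])
                )
    return pd.DataFrame(
        rows, columns=["time_index", "condition", "marker", "coord1", "coord2"]
    )
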