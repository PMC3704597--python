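"""Raw-trial preprocessing: filter, stance crop, time normalize, center, scale.

The fixed pipeline order is filter -> stance crop -> time normalization ->
centering/height scaling.  Filtering before cropping keeps the filter's edge
transients away from the stance window.

Defaults follow standard running-gait practice: zero-phase 4th-order
Butterworth low-pass at 12 Hz on 240 Hz data, 15 N vertical-force threshold
for initial contact and toe-off, 101 equidistant normalized time points over
stance, pelvis-centroid centering in the transversal (horizontal) plane,
floor-referenced vertical, and division by body height (dimensionless output).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .errors import NoStanceError
from .layout import TrialRecord

__all__ = [
    "detect_stance",
    "lowpass_filter",
    "time_normalize",
    "center_and_scale",
    "PreprocessConfig",
    "preprocess_trial",
]


def detect_stance(force: np.ndarray, threshold: float = 15.0) -> tuple[int, int]:
    """Locate stance in a vertical ground-reaction-force trace.

    Returns 0-based (contact, toe_off) frame indices: contact is the first
    frame at or above ``threshold`` newtons and toe_off the last frame of the
    contiguous supra-threshold episode starting there.  Multiple disjoint
    episodes trigger a warning; the first is used.
    """
    force = np.asarray(force, dtype=float)
    if force.size == 0:
        raise ValueError("force trace is empty")
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    above = force >= threshold
    if not above.any():
        raise NoStanceError(f"no frame reaches the {threshold} N threshold")
    contact = int(np.argmax(above))
    below_after = ~above[contact:]
    toe_off = contact + (int(np.argmax(below_after)) - 1 if below_after.any() else len(force) - 1 - contact)
    if above[toe_off + 1 :].any():
        warnings.warn(
            "multiple supra-threshold episodes in force trace; using the first",
            stacklevel=2,
        )
    if contact >= toe_off:
        raise NoStanceError("stance episode shorter than two frames")
    return contact, toe_off


def lowpass_filter(
    trajectory: np.ndarray,
    cutoff: float = 12.0,
    order: int = 4,
    sample_rate: float = 240.0,
    zero_phase: bool = True,
) -> np.ndarray:
    """Low-pass Butterworth filter along the first (time) axis.

    Zero-phase by default: the filter is applied forward and backward
    (``filtfilt``) with the per-pass order halved so the net magnitude
    response has the stated ``order``; features are not shifted in time.
    ``zero_phase=False`` applies a single causal pass of the full order.
    """
    x = np.asarray(trajectory, dtype=float)
    if not 0 < cutoff < sample_rate / 2:
        raise ValueError(f"cutoff must lie in (0, {sample_rate / 2}) Hz")
    if order < 2 or order % 2:
        raise ValueError("order must be a positive even integer")
    if x.shape[0] < 3 * order:
        raise ValueError(f"series length {x.shape[0]} < 3 x order ({3 * order})")
    if zero_phase:
        sos = signal.butter(order // 2, cutoff, fs=sample_rate, output="sos")
        return signal.sosfiltfilt(sos, x, axis=0)
    sos = signal.butter(order, cutoff, fs=sample_rate, output="sos")
    return signal.sosfilt(sos, x, axis=0)


def time_normalize(segment: np.ndarray, timepoints: int = 101) -> np.ndarray:
    """Resample a stance segment to equidistant normalized time points.

    Cubic-spline interpolation along the first axis; the first/last output
    samples coincide exactly with the segment endpoints (contact, toe-off).
    """
    x = np.asarray(segment, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("segment must have >= 2 frames")
    t = np.arange(x.shape[0], dtype=float)
    t_out = np.linspace(0.0, x.shape[0] - 1.0, timepoints)
    if x.shape[0] < 4:  # cubic needs 4 points; degrade gracefully
        from scipy.interpolate import make_interp_spline

        return make_interp_spline(t, x, k=x.shape[0] - 1, axis=0)(t_out)
    return CubicSpline(t, x, axis=0)(t_out)


def center_and_scale(
    trial: TrialRecord,
    pelvis_markers: tuple[int, ...] = (1, 2, 3, 4),
    height: float = 1.0,
    vertical_axis: int = 3,
    per_frame: bool = True,
) -> TrialRecord:
    """Shift to the pelvis center (transversal plane) and floor, scale by height.

    Horizontal coordinates are shifted by the centroid of ``pelvis_markers``
    (1-based), per frame by default or by the trial-mean centroid; the
    vertical coordinate is shifted by a constant so the trial's lowest marker
    position is 0 (floor); everything is divided by ``height`` (meters), so
    the output is dimensionless.
    """
    if not pelvis_markers:
        raise ValueError("pelvis_markers must be non-empty")
    if height <= 0:
        raise ValueError("height must be > 0")
    pos = trial.positions.copy()
    v = vertical_axis - 1
    horiz = [a for a in range(pos.shape[2]) if a != v]
    pel = np.array([m - 1 for m in pelvis_markers])
    centroid = pos[:, pel, :].mean(axis=1)  # (frames, axes)
    if not per_frame:
        centroid = np.broadcast_to(centroid.mean(axis=0), centroid.shape)
    for a in horiz:
        pos[:, :, a] -= centroid[:, a][:, None]
    pos[:, :, v] -= pos[:, :, v].min()
    pos /= height
    return replace(trial, positions=pos)


@dataclass
class PreprocessConfig:
    """Knobs of the raw-trial pipeline (defaults = standard gait practice)."""

    cutoff_hz: float = 12.0
    filter_order: int = 4
    zero_phase: bool = True
    stance_threshold_n: float = 15.0
    timepoints: int = 101
    pelvis_markers: tuple[int, ...] = (1, 2, 3, 4)
    vertical_axis: int = 3
    per_frame_centering: bool = True
    height_m: dict[str, float] = field(default_factory=dict)  # per subject


def preprocess_trial(trial: TrialRecord, config: PreprocessConfig | None = None) -> TrialRecord:
    """Run the full pipeline on one raw trial (requires a force trace).

    Order: low-pass filter -> stance crop from the force trace -> resample to
    ``timepoints`` -> pelvis centering / floor shift / height scaling.
    A force trace sampled faster than the kinematics is decimated to the
    kinematic frame clock by nearest-frame lookup before thresholding.
    """
    cfg = config or PreprocessConfig()
    if trial.force is None:
        raise ValueError(f"{trial.key}: stance detection requires a force trace")
    force = trial.force
    if len(force) != trial.n_frames:
        # nearest-frame lookup onto the kinematic clock
        src = np.linspace(0, 1, len(force))
        dst = np.linspace(0, 1, trial.n_frames)
        force = force[np.abs(src[None, :] - dst[:, None]).argmin(axis=1)]
    filtered = lowpass_filter(
        trial.positions,
        cutoff=cfg.cutoff_hz,
        order=cfg.filter_order,
        sample_rate=trial.sample_rate,
        zero_phase=cfg.zero_phase,
    )
    contact, toe_off = detect_stance(force, cfg.stance_threshold_n)
    stance = filtered[contact : toe_off + 1]
    normalized = time_normalize(stance, cfg.timepoints)
    out = TrialRecord(
        key=trial.key,
        positions=normalized,
        sample_rate=trial.sample_rate,
        force=None,
    )
    height = cfg.height_m.get(trial.key.subject, 1.0)
    return center_and_scale(
        out,
        pelvis_markers=cfg.pelvis_markers,
        height=height,
        vertical_axis=cfg.vertical_axis,
        per_frame=cfg.per_frame_centering,
    )
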