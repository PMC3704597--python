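"""Kinematic data matrix: trial records, column layout and assembly.

Every trial of a two-condition (dichotomous) movement experiment is one row of
the data matrix.  A row concatenates the time-normalized 3-D trajectories of
all markers: first the 101 x-positions of marker 1, then its 101 y-positions,
then z, then marker 2, and so on.  With 13 markers, 3 axes and 101 normalized
time points a row has 13*3*101 = 3939 variables, and a study of 11 subjects x
2 conditions x 20 trials yields a 440 x 3939 matrix.

Column indices are reported 1-based throughout the public API, matching the
convention of the field ("variable 847" is marker 3, vertical axis, time 39).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import EmptyDataError, ShapeError

__all__ = [
    "TrialKey",
    "TrialRecord",
    "IndexMap",
    "AssembledMatrix",
    "Waveform",
    "assemble_matrix",
    "extract_waveform",
]


@dataclass(frozen=True, order=True)
class TrialKey:
    """Identity of one trial: (subject, condition, trial index)."""

    subject: str
    condition: str
    trial: int

    def __post_init__(self) -> None:
        if self.trial < 1:
            raise ValueError(f"trial index must be positive, got {self.trial}")


@dataclass
class TrialRecord:
    """One trial's marker trajectories.

    Parameters
    ----------
    key
        Subject / condition / trial identity.
    positions
        Array of shape ``(frames, markers, 3)`` in meters (or height-normalized
        units after preprocessing).
    sample_rate
        Sampling frequency in Hz; 240 Hz for typical optical motion capture.
        After time normalization the frame axis holds 101 equidistant samples
        of the stance phase and the rate is nominal.
    force
        Optional vertical ground-reaction-force trace in newtons, aligned to
        the kinematic frame clock (or sampled faster; see preprocessing).
    """

    key: TrialKey
    positions: np.ndarray
    sample_rate: float = 240.0
    force: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3:
            raise ShapeError(
                f"{self.key}: positions must be (frames, markers, axes), "
                f"got shape {self.positions.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError(f"{self.key}: sample_rate must be > 0")
        if self.force is not None:
            self.force = np.asarray(self.force, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def n_axes(self) -> int:
        return self.positions.shape[2]


@dataclass(frozen=True)
class IndexMap:
    """Bijection between (marker, axis, time) and the flat column index.

    The flat layout is marker-major, then axis, then time.  All user-facing
    indices are 1-based; :meth:`column` of (3, 3, 39) under the default
    13/3/101 layout is 847.
    """

    markers: int = 13
    axes: int = 3
    timepoints: int = 101

    def __post_init__(self) -> None:
        if min(self.markers, self.axes, self.timepoints) < 1:
            raise ValueError("IndexMap dimensions must all be >= 1")

    @property
    def num_variables(self) -> int:
        return self.markers * self.axes * self.timepoints

    def _check(self, marker: int, axis: int, time: int) -> None:
        if not (1 <= marker <= self.markers):
            raise IndexError(f"marker {marker} out of range 1..{self.markers}")
        if not (1 <= axis <= self.axes):
            raise IndexError(f"axis {axis} out of range 1..{self.axes}")
        if not (1 <= time <= self.timepoints):
            raise IndexError(f"time {time} out of range 1..{self.timepoints}")

    def column(self, marker: int, axis: int, time: int) -> int:
        """1-based flat column index of (marker, axis, time), all 1-based."""
        self._check(marker, axis, time)
        return ((marker - 1) * self.axes + (axis - 1)) * self.timepoints + time

    def inverse(self, column: int) -> tuple[int, int, int]:
        """Recover 1-based (marker, axis, time) from a 1-based column index."""
        if not (1 <= column <= self.num_variables):
            raise IndexError(f"column {column} out of range 1..{self.num_variables}")
        c = column - 1
        marker, rest = divmod(c, self.axes * self.timepoints)
        axis, time = divmod(rest, self.timepoints)
        return marker + 1, axis + 1, time + 1

    def block_slice(self, marker: int, axis: int) -> slice:
        """0-based Python slice of the contiguous time block for (marker, axis)."""
        self._check(marker, axis, 1)
        start = self.column(marker, axis, 1) - 1
        return slice(start, start + self.timepoints)


@dataclass
class Waveform:
    """Time course(s) of one marker along one axis over normalized stance.

    ``series`` has one row per trial (101 columns by default).  ``sd`` is only
    set for condition-averaged waveforms, aligned to ``series`` rows.
    """

    marker: int
    axis: int
    series: np.ndarray
    keys: Sequence[TrialKey] | None = None
    conditions: Sequence[str] | None = None
    sd: np.ndarray | None = None


@dataclass
class AssembledMatrix:
    """Trials x variables matrix with its row metadata and column layout."""

    values: np.ndarray
    row_meta: list[TrialKey]
    layout: IndexMap
    whitened: bool = False
    subject_stats: "SubjectStats | None" = None  # set by whitening

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"matrix must be 2-D, got shape {self.values.shape}")
        if self.values.shape[1] != self.layout.num_variables:
            raise ShapeError(
                f"matrix has {self.values.shape[1]} columns but layout implies "
                f"{self.layout.num_variables}"
            )
        if len(self.row_meta) != self.values.shape[0]:
            raise ShapeError(
                f"{len(self.row_meta)} row keys for {self.values.shape[0]} rows"
            )

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def subjects(self) -> list[str]:
        """Distinct subjects in first-appearance order."""
        seen: dict[str, None] = {}
        for k in self.row_meta:
            seen.setdefault(k.subject, None)
        return list(seen)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for k in self.row_meta:
            seen.setdefault(k.condition, None)
        return list(seen)

    @property
    def labels(self) -> np.ndarray:
        """Condition label per row."""
        return np.array([k.condition for k in self.row_meta])

    @property
    def groups(self) -> np.ndarray:
        """Subject identifier per row (grouping for leave-one-subject-out)."""
        return np.array([k.subject for k in self.row_meta])

    def with_values(self, values: np.ndarray, **changes) -> "AssembledMatrix":
        """Copy with new values (and optional field overrides)."""
        return replace(self, values=np.asarray(values, dtype=float), **changes)


def assemble_matrix(trials: Iterable[TrialRecord], layout: IndexMap | None = None) -> AssembledMatrix:
    """Stack preprocessed trials into the trials x variables data matrix.

    Every trial must already be time-normalized to ``layout.timepoints`` frames
    and carry the same marker and axis counts.  Rows follow the iteration
    order of ``trials``; columns follow the marker-major layout of
    :class:`IndexMap`.

    Raises
    ------
    EmptyDataError
        If ``trials`` is empty.
    ShapeError
        If a trial's shape disagrees with the layout; the message names the
        offending :class:`TrialKey`.
    """
    trials = list(trials)
    if not trials:
        raise EmptyDataError("assemble_matrix received no trials")
    first = trials[0]
    if layout is None:
        layout = IndexMap(
            markers=first.n_markers, axes=first.n_axes, timepoints=first.n_frames
        )
    expected = (layout.timepoints, layout.markers, layout.axes)
    rows = np.empty((len(trials), layout.num_variables))
    seen: set[TrialKey] = set()
    for i, t in enumerate(trials):
        if t.positions.shape != expected:
            raise ShapeError(
                f"trial {t.key} has shape {t.positions.shape}, expected {expected}"
            )
        if t.key in seen:
            raise ShapeError(f"duplicate trial key {t.key}")
        seen.add(t.key)
        # (time, marker, axis) -> (marker, axis, time) then flatten
        rows[i] = t.positions.transpose(1, 2, 0).reshape(-1)
    return AssembledMatrix(rows, [t.key for t in trials], layout, whitened=False)


def extract_waveform(matrix: AssembledMatrix, marker: int, axis: int) -> Waveform:
    """Per-trial waveform of one marker along one axis (101 columns)."""
    sl = matrix.layout.block_slice(marker, axis)
    return Waveform(
        marker=marker,
        axis=axis,
        series=matrix.values[:, sl].copy(),
        keys=list(matrix.row_meta),
    )


def condition_average_waveform(matrix: AssembledMatrix, marker: int, axis: int) -> Waveform:
    """Condition-averaged waveform: mean and per-time-point SD per condition."""
    wf = extract_waveform(matrix, marker, axis)
    labels = matrix.labels
    conds = matrix.conditions
    means = np.stack([wf.series[labels == c].mean(axis=0) for c in conds])
    sds = np.stack([wf.series[labels == c].std(axis=0, ddof=1) for c in conds])
    return Waveform(marker=marker, axis=axis, series=means, conditions=conds, sd=sds)
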