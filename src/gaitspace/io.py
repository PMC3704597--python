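"""Plain-text I/O: long-format trial CSVs and the matrix exchange format.

Long format (input): one CSV with header
``subject,condition,trial,frame,marker,x,y,z``, one row per frame x marker,
positions in meters.  Optional per-trial force CSVs with header
``frame,fz_newton``.

Exchange format (assembled matrix): a headerless numeric CSV (one row per
trial) plus a JSON sidecar holding the ordered row keys, layout parameters,
whitening flag and, when whitened, the per-subject statistics.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .layout import AssembledMatrix, IndexMap, TrialKey, TrialRecord
from .whitening import SubjectStats

__all__ = [
    "read_trials_csv",
    "write_trials_csv",
    "read_force_csv",
    "write_matrix",
    "read_matrix",
]


def read_trials_csv(path, sample_rate: float = 240.0) -> list[TrialRecord]:
    """Read long-format trials; markers and frames may start at 0 or 1."""
    df = pd.read_csv(path)
    required = {"subject", "condition", "trial", "frame", "marker", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns in {path}: {sorted(missing)}")
    trials: list[TrialRecord] = []
    for (subj, cond, trial), g in df.groupby(["subject", "condition", "trial"], sort=False):
        frames = np.sort(g["frame"].unique())
        markers = np.sort(g["marker"].unique())
        pos = np.full((len(frames), len(markers), 3), np.nan)
        fi = {f: i for i, f in enumerate(frames)}
        mi = {m: i for i, m in enumerate(markers)}
        for row in g.itertuples(index=False):
            pos[fi[row.frame], mi[row.marker]] = (row.x, row.y, row.z)
        if np.isnan(pos).any():
            raise ValueError(
                f"trial ({subj}, {cond}, {trial}) has missing frame/marker rows"
            )
        trials.append(
            TrialRecord(
                key=TrialKey(str(subj), str(cond), int(trial)),
                positions=pos,
                sample_rate=sample_rate,
            )
        )
    return trials


def write_trials_csv(trials: list[TrialRecord], path) -> None:
    rows = []
    for t in trials:
        for f in range(t.n_frames):
            for m in range(t.n_markers):
                rows.append(
                    (
                        t.key.subject,
                        t.key.condition,
                        t.key.trial,
                        f + 1,
                        m + 1,
                        *t.positions[f, m],
                    )
                )
    pd.DataFrame(
        rows, columns=["subject", "condition", "trial", "frame", "marker", "x", "y", "z"]
    ).to_csv(path, index=False)


def read_force_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "fz_newton" not in df.columns:
        raise ValueError(f"{path} lacks an fz_newton column")
    return df.sort_values("frame")["fz_newton"].to_numpy(dtype=float)


def write_matrix(matrix: AssembledMatrix, csv_path, sidecar_path=None) -> None:
    """Write the exchange format: numeric CSV + JSON sidecar."""
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    np.savetxt(csv_path, matrix.values, delimiter=",")
    meta = {
        "row_meta": [
            {"subject": k.subject, "condition": k.condition, "trial": k.trial}
            for k in matrix.row_meta
        ],
        "layout": {
            "markers": matrix.layout.markers,
            "axes": matrix.layout.axes,
            "timepoints": matrix.layout.timepoints,
        },
        "whitened": matrix.whitened,
    }
    if matrix.subject_stats is not None:
        st = matrix.subject_stats
        meta["subject_stats"] = {
            "ddof": st.ddof,
            "mean": {s: v.tolist() for s, v in st.mean.items()},
            "std": {s: v.tolist() for s, v in st.std.items()},
            "degenerate": {s: v.tolist() for s, v in st.degenerate.items()},
        }
    sidecar_path.write_text(json.dumps(meta))


def read_matrix(csv_path, sidecar_path=None) -> AssembledMatrix:
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    meta = json.loads(sidecar_path.read_text())
    stats = None
    if "subject_stats" in meta:
        st = meta["subject_stats"]
        stats = SubjectStats(
            mean={s: np.asarray(v) for s, v in st["mean"].items()},
            std={s: np.asarray(v) for s, v in st["std"].items()},
            ddof=st.get("ddof", 1),
            degenerate={s: np.asarray(v, dtype=bool) for s, v in st.get("degenerate", {}).items()},
        )
    return AssembledMatrix(
        values=values,
        row_meta=[TrialKey(d["subject"], d["condition"], d["trial"]) for d in meta["row_meta"]],
        layout=IndexMap(**meta["layout"]),
        whitened=bool(meta["whitened"]),
        subject_stats=stats,
    )
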