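"""Time-series preparation: ROI extraction, normalization, condition segmentation.

The upstream acquisition yields, per subject, several runs of a frames x ROI
BOLD matrix sampled every TR seconds, together with a frame-wise task
schedule (conditions: self-initiated movement "SI", externally triggered
"ET", control "CTL", and "rest"). This module turns those runs into the
condition-specific concatenated matrices the network analysis consumes, and
computes the subject-level subcortical activity index and mean response time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi import subcortical_names

logger = logging.getLogger(__name__)

CONDITIONS = ("SI", "ET", "CTL", "rest")


@dataclass
class SubjectTimeSeries:
    """Per-subject ROI time series: ordered runs plus the task schedule.

    ``runs[r]`` is a frames x ROI float array; ``schedule[r]`` is a
    same-length array of condition labels; ``tr_seconds`` the sampling
    interval.
    """

    runs: list[np.ndarray]
    roi_names: list[str]
    tr_seconds: float
    schedule: list[np.ndarray]

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        n_roi = len(self.roi_names)
        if len(self.runs) != len(self.schedule):
            raise ValueError("one schedule per run required")
        for r, (mat, sched) in enumerate(zip(self.runs, self.schedule)):
            if mat.ndim != 2 or mat.shape[1] != n_roi:
                raise ValueError(f"run {r}: expected frames x {n_roi} matrix")
            if len(sched) != mat.shape[0]:
                raise ValueError(f"run {r}: schedule does not cover every frame")

    @property
    def n_runs(self) -> int:
        return len(self.runs)


@dataclass
class ConditionMatrix:
    """Frames of one condition, trimmed and concatenated across blocks/runs."""

    data: np.ndarray  # retained-frames x ROI
    roi_names: list[str]
    condition: str
    frames_dropped_per_block: int


def extract_roi_timeseries(
    volume: np.ndarray, affine: np.ndarray, roi_table: pd.DataFrame
) -> np.ndarray:
    """Average 3x3x3-voxel cubes centred on each ROI peak, per frame.

    Peaks are given in millimetre coordinates; the affine maps voxel indices
    to mm and is inverted with nearest-voxel rounding. Each ROI's series is
    the mean over its 27 cube voxels.

    Returns a frames x ROI array (ROI order = table order).
    """
    if volume.ndim != 4:
        raise ValueError("expected a 4-D volume (x, y, z, t)")
    if affine.shape != (4, 4):
        raise ValueError("affine must be 4x4")
    try:
        inv = np.linalg.inv(affine)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-invertible affine") from exc

    nx, ny, nz, n_frames = volume.shape
    out = np.empty((n_frames, len(roi_table)))
    for k, row in roi_table.iterrows():
        mm = np.array([row["x"], row["y"], row["z"], 1.0])
        vox = np.rint(inv @ mm)[:3].astype(int)
        lo, hi = vox - 1, vox + 1
        if (lo < 0).any() or (hi >= np.array([nx, ny, nz])).any():
            raise ValueError(
                f"ROI {row['name']!r}: 27-voxel cube at voxel {vox.tolist()} "
                "extends outside the volume"
            )
        cube = volume[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1, :]
        out[:, k] = cube.reshape(27, n_frames).mean(axis=0)
    return out


def normalize_run(run: np.ndarray) -> np.ndarray:
    """Globally z-score one run using the pooled mean/SD of ALL its entries.

    Pooling is over every value of the frames x ROI matrix (e.g. 146 x 62 =
    9052 values), not per column; the sample (n-1) SD is used. The output has
    pooled mean 0 and pooled SD 1.
    """
    values = np.asarray(run, dtype=float)
    mean = values.mean()
    sd = values.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("constant run matrix: pooled SD is zero")
    return (values - mean) / sd


def trim_frames(trim_seconds: float, tr_seconds: float) -> int:
    """Frames to drop at each block onset: ceil(trim / TR).

    Guarantees at least ``trim_seconds`` of post-onset hemodynamic delay is
    discarded (10 s at TR 3.5 s -> 3 frames).
    """
    if trim_seconds < 0 or tr_seconds <= 0:
        raise ValueError("trim_seconds >= 0 and tr_seconds > 0 required")
    return math.ceil(trim_seconds / tr_seconds)


def _condition_blocks(schedule: np.ndarray, condition: str):
    """Yield (start, stop) of maximal contiguous same-condition frame blocks."""
    mask = np.asarray(schedule) == condition
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([0], breaks + 1))
    stops = np.concatenate((breaks, [idx.size - 1]))
    for s, e in zip(starts, stops):
        yield int(idx[s]), int(idx[e]) + 1


def segment_and_concatenate(
    subject: SubjectTimeSeries, condition: str, trim_seconds: float = 10.0
) -> ConditionMatrix:
    """Extract one condition's frames, trimming each block onset.

    Within each contiguous same-condition block the first
    ``ceil(trim_seconds / TR)`` frames are dropped (hemodynamic delay);
    surviving frames are concatenated across blocks and runs in temporal
    order. A block shorter than the trim contributes no frames (a warning is
    logged, not raised).
    """
    present = any(
        (np.asarray(s) == condition).any() for s in subject.schedule
    )
    if not present:
        raise ValueError(f"condition {condition!r} absent from schedule")
    n_drop = trim_frames(trim_seconds, subject.tr_seconds)
    pieces = []
    for r, (mat, sched) in enumerate(zip(subject.runs, subject.schedule)):
        for start, stop in _condition_blocks(sched, condition):
            kept = mat[start + n_drop : stop, :]
            if kept.shape[0] == 0:
                logger.warning(
                    "run %d: %s block of %d frames shorter than %d-frame trim; "
                    "contributes no frames",
                    r,
                    condition,
                    stop - start,
                    n_drop,
                )
            else:
                pieces.append(kept)
    data = (
        np.concatenate(pieces, axis=0)
        if pieces
        else np.empty((0, len(subject.roi_names)))
    )
    return ConditionMatrix(
        data=data,
        roi_names=list(subject.roi_names),
        condition=condition,
        frames_dropped_per_block=n_drop,
    )


def subcortical_activity_index(
    cond: ConditionMatrix, roi_table: pd.DataFrame
) -> pd.Series:
    """Mean normalized signal of each subcortical ROI over retained frames.

    The per-subject average of the normalized SI time series in the 10
    subcortical ROIs (caudate, putamen, ventral striatum, thalamus) serves as
    an index of regional activity during the task.
    """
    if cond.data.shape[0] == 0:
        raise ValueError("empty condition matrix")
    names = subcortical_names(roi_table)
    missing = [n for n in names if n not in cond.roi_names]
    if missing:
        raise ValueError(f"subcortical ROIs absent from matrix: {missing}")
    cols = [cond.roi_names.index(n) for n in names]
    return pd.Series(cond.data[:, cols].mean(axis=0), index=names, name="activity")


def mean_rt(events: pd.DataFrame, condition: str) -> float:
    """Mean inter-press interval (ms) for one subject and condition.

    The response time is the interval between the onsets of successive
    button presses. Differences are taken within each (run, block) press
    sequence — never across block or run boundaries — and pooled over hands,
    blocks, and runs.

    ``events`` needs columns ``run, condition, block, time_ms``.
    """
    sel = events.loc[events["condition"] == condition]
    intervals: list[np.ndarray] = []
    for _, grp in sel.groupby(["run", "block"]):
        t = np.sort(grp["time_ms"].to_numpy(dtype=float))
        if t.size >= 2:
            intervals.append(np.diff(t))
    if not intervals:
        raise ValueError(
            f"fewer than 2 presses in condition {condition!r}; RT undefined"
        )
    return float(np.concatenate(intervals).mean())
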