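"""Volume repair, detrending, standardization and block averaging.

The pipeline order is fixed: outlier repair -> median-filter detrending ->
per-run voxel standardization -> block averaging. Outliers are volumes whose
global mean intensity deviates more than 3 SDs from the run average or whose
volume-to-volume translation exceeds 2 mm; they are replaced by linear
interpolation of the nearest non-repaired volumes. Participants with more
than 20% outlier volumes in any usable run are excluded. Classification
samples are the mean of five TRs per task block, shifted 6 s after block
onset to account for the hemodynamic delay; fixation blocks never become
samples.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .dataset import FIXATION, ParticipantData, RunData, SampleSet

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_roll", "rot_pitch", "rot_yaw")


def detect_outlier_volumes(
    timeseries: np.ndarray,
    motion: np.ndarray,
    intensity_sd_threshold: float = 3.0,
    motion_mm_threshold: float = 2.0,
) -> np.ndarray:
    """Flag volumes by global-intensity deviation or volume-to-volume motion.

    A volume is an outlier if its global mean deviates from the run mean of
    global means by more than ``intensity_sd_threshold`` run SDs, or if the
    Euclidean displacement of the three translation parameters from the
    previous volume exceeds ``motion_mm_threshold`` mm. Rotations are not
    part of the displacement (the criterion is stated in mm); the first
    volume can never be motion-flagged.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.shape[0] < 3:
        raise ValueError("need at least 3 volumes")
    g = ts.mean(axis=1)
    sd = g.std()
    if sd > 0:
        flags = np.abs(g - g.mean()) > intensity_sd_threshold * sd
    else:
        flags = np.zeros(len(g), dtype=bool)
    trans = np.asarray(motion, dtype=float)[:, :3]
    disp = np.linalg.norm(np.diff(trans, axis=0), axis=1)
    flags[1:] |= disp > motion_mm_threshold
    return flags


def repair_outliers(timeseries: np.ndarray, flags: np.ndarray) -> np.ndarray:
    """Replace flagged volumes by interpolating the nearest non-repaired ones.

    Interior flagged volumes are linearly interpolated (in time index)
    between the nearest earlier and later unflagged volumes; flagged volumes
    at the run edges copy the nearest unflagged volume.
    """
    ts = np.asarray(timeseries, dtype=float)
    flags = np.asarray(flags, dtype=bool)
    if flags.all():
        raise ValueError("all volumes flagged: run is unrecoverable")
    if not flags.any():
        return ts.copy()
    out = ts.copy()
    good = np.flatnonzero(~flags)
    for t in np.flatnonzero(flags):
        after = good[good > t]
        before = good[good < t]
        if len(before) == 0:
            out[t] = ts[after[0]]
        elif len(after) == 0:
            out[t] = ts[before[-1]]
        else:
            a, b = before[-1], after[0]
            frac = (t - a) / (b - a)
            out[t] = (1.0 - frac) * ts[a] + frac * ts[b]
    return out


def exclusion_check(flags_per_run: list, max_fraction: float = 0.20):
    """Exclude a participant iff any run has MORE than ``max_fraction`` outliers.

    Returns ``(exclude, reason)``; exactly 20% is kept.
    """
    for i, flags in enumerate(flags_per_run):
        frac = float(np.mean(flags))
        if frac > max_fraction:
            return True, f"run {i}: {frac:.1%} outlier volumes (> {max_fraction:.0%})"
    return False, ""


def remove_drift(timeseries: np.ndarray, tr_s: float, window_s: float = 120.0) -> np.ndarray:
    """Subtract a running median over a centred window (default 120 s).

    The window is ``round(window_s / tr_s)`` volumes, forced odd; at the run
    edges the median is taken over the truncated (clipped) window. If the
    window covers the whole run, the global median is subtracted.
    """
    ts = np.asarray(timeseries, dtype=float)
    T = ts.shape[0]
    w = int(round(window_s / tr_s))
    if w % 2 == 0:
        w += 1
    if w >= T:
        return ts - np.median(ts, axis=0, keepdims=True)
    h = w // 2
    baseline = median_filter(ts, size=(w, 1), mode="nearest")
    # redo edges with truncated windows (median_filter pads instead)
    for t in range(h):
        baseline[t] = np.median(ts[: t + h + 1], axis=0)
        baseline[T - 1 - t] = np.median(ts[T - 1 - t - h :], axis=0)
    return ts - baseline


def standardize(timeseries: np.ndarray) -> np.ndarray:
    """Per-voxel z-scoring within the run: mean 0, unit variance.

    Zero-variance voxels are set to zero rather than dividing by zero.
    """
    ts = np.asarray(timeseries, dtype=float)
    mean = ts.mean(axis=0, keepdims=True)
    sd = ts.std(axis=0, keepdims=True)
    out = ts - mean
    nz = sd[0] > 0
    out[:, nz] /= sd[0][nz]
    out[:, ~nz] = 0.0
    return out


def block_average(
    timeseries: np.ndarray,
    events: pd.DataFrame,
    tr_s: float,
    delay_s: float = 6.0,
    n_trs: int = 5,
):
    """Average ``n_trs`` volumes per task block, starting ``delay_s`` after onset.

    The first index for a block with onset ``t`` is ``floor((t + delay_s) /
    tr_s)`` (floor: never samples pre-onset signal). Fixation blocks are
    skipped. Blocks whose window would run past the end of the run are
    dropped with a warning; the number of drops is returned.

    Returns
    -------
    features : (S, V) array
    condition : (S,) array of task condition labels
    n_dropped : int
    """
    ts = np.asarray(timeseries, dtype=float)
    T = ts.shape[0]
    feats, labels = [], []
    n_dropped = 0
    for _, row in events.iterrows():
        if row["trial_type"] == FIXATION:
            continue
        start = int(math.floor((row["onset"] + delay_s) / tr_s))
        stop = start + n_trs
        if start < 0 or stop > T:
            n_dropped += 1
            continue
        feats.append(ts[start:stop].mean(axis=0))
        labels.append(row["trial_type"])
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} block(s) whose sample window left the run")
    features = np.asarray(feats) if feats else np.empty((0, ts.shape[1]))
    return features, np.asarray(labels), n_dropped


@dataclass
class QCReport:
    """Per-participant preprocessing bookkeeping."""

    excluded: dict = field(default_factory=dict)  # pid -> reason
    outlier_fraction: dict = field(default_factory=dict)  # (pid, fmt, run) -> fraction
    dropped_samples: int = 0
    motion_summary: pd.DataFrame = None  # pid x 6 mean absolute motion


def preprocess_participant(participant: ParticipantData, delay_s: float = 6.0, n_trs: int = 5):
    """Run the full pipeline on one participant.

    Returns ``(sample_set or None, qc_rows, excluded_reason, n_dropped)``.
    The sample set pools all runs of all formats; per run it contains exactly
    one sample per task block (ten per condition in the emulated design,
    minus dropped windows).
    """
    flags_per_run = []
    keys = sorted(participant.runs)
    for key in keys:
        run = participant.runs[key]
        flags_per_run.append(detect_outlier_volumes(run.timeseries, run.motion))
    exclude, reason = exclusion_check(flags_per_run)
    if exclude:
        return None, {}, reason, 0

    parts = []
    qc = {}
    total_dropped = 0
    for key, flags in zip(keys, flags_per_run):
        fmt, run_idx = key
        run = participant.runs[key]
        ts = repair_outliers(run.timeseries, flags)
        ts = remove_drift(ts, run.tr_s)
        ts = standardize(ts)
        features, condition, dropped = block_average(ts, run.events, run.tr_s, delay_s, n_trs)
        total_dropped += dropped
        qc[(participant.participant_id, fmt, run_idx)] = float(np.mean(flags))
        if len(features) == 0:
            continue
        S = len(features)
        parts.append(
            SampleSet(
                features,
                condition,
                np.repeat(participant.participant_id, S),
                np.repeat(fmt, S),
                np.repeat(run_idx, S),
            )
        )
    samples = SampleSet.concat(parts) if parts else None
    return samples, qc, "", total_dropped


def build_samples(participants: list, delay_s: float = 6.0, n_trs: int = 5):
    """Preprocess a whole dataset into one pooled :class:`SampleSet`.

    Returns ``(samples, participants_table, qc)``. ``participants_table`` has
    one row per retained participant: id, group, IQ and the six mean-absolute
    motion summaries (used downstream as covariates).
    """
    parts = []
    qc = QCReport()
    rows = []
    for p in participants:
        samples, run_qc, reason, dropped = preprocess_participant(p, delay_s=delay_s, n_trs=n_trs)
        if reason:
            qc.excluded[p.participant_id] = reason
            continue
        qc.outlier_fraction.update(run_qc)
        qc.dropped_samples += dropped
        if samples is None:
            qc.excluded[p.participant_id] = "no usable samples"
            continue
        parts.append(samples)
        motion = np.vstack([run.motion for run in p.runs.values()])
        summary = np.abs(motion).mean(axis=0)
        rows.append(
            {"participant_id": p.participant_id, "group": p.group, "iq": p.iq}
            | dict(zip(MOTION_COLUMNS, summary))
        )
    if not parts:
        raise ValueError("every participant was excluded")
    table = pd.DataFrame(rows).set_index("participant_id")
    qc.motion_summary = table[list(MOTION_COLUMNS)]
    return SampleSet.concat(parts), table, qc
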