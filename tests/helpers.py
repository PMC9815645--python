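"""Shared builders for hand-made grids and sample sets."""

import numpy as np

from mvpa_adapt.dataset import ADAPTATION, NO_ADAPTATION, SampleSet
from mvpa_adapt.grid import VolumeGrid


def full_grid(shape=(3, 3, 3), voxel_size_mm=2.0):
    """Grid whose mask covers every voxel."""
    return VolumeGrid(shape, voxel_size_mm, np.ones(shape, dtype=bool))


def make_sample_set(
    rng,
    pids,
    fmts=("f1",),
    n_per_condition=6,
    n_voxels=27,
    effect=0.0,
    effect_cols=None,
    pattern=None,
    run_index=0,
):
    """Hand-built SampleSet: iid Gaussian features plus an optional planted
    condition contrast (same pattern for every participant and format)."""
    feats, cond, pid_col, fmt_col, run_col = [], [], [], [], []
    if effect and pattern is None:
        pattern = np.ones(len(effect_cols))
    for pid in pids:
        for fmt in fmts:
            for c in (ADAPTATION, NO_ADAPTATION):
                for _ in range(n_per_condition):
                    x = rng.standard_normal(n_voxels)
                    if effect:
                        sign = 0.5 if c == NO_ADAPTATION else -0.5
                        x[effect_cols] += sign * effect * pattern
                    feats.append(x)
                    cond.append(c)
                    pid_col.append(pid)
                    fmt_col.append(fmt)
                    run_col.append(run_index)
    return SampleSet(
        np.asarray(feats), np.asarray(cond), np.asarray(pid_col),
        np.asarray(fmt_col), np.asarray(run_col),
    )
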