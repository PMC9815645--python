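"""Synthetic multi-participant fMRI-adaptation datasets with known ground truth.

The generator emulates a passive block-design adaptation experiment: per run,
``blocks_per_condition`` adaptation blocks, the same number of no-adaptation
blocks and of fixation blocks (9.6 s each, TR 2 s), pseudorandomized so that
two blocks of the same type never follow each other. Repetition suppression
is modelled as a condition contrast planted in configurable gray-matter
regions: the expected voxel pattern during adaptation blocks is lower than
during no-adaptation blocks by a mean shift plus a zero-mean multivariate
pattern, convolved with a delayed boxcar response (the analysis consumes
block averages, so a full hemodynamic model adds nothing downstream).

Cross-participant decodability is controlled per region: each participant's
pattern is ``sqrt(c) * shared + sqrt(1 - c) * idiosyncratic`` where ``c`` is
the cross-participant consistency. Regions can express the same pattern in
several stimulus formats (a format-independent representation) or draw
independent patterns per format, and can be restricted to one age group —
together these operationalize format-shared vs format-distinct coding by age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ADAPTATION, FIXATION, NO_ADAPTATION, ParticipantData, RunData
from .grid import VolumeGrid, ball_mask, ellipsoid_mask

_SHARED_KEY = "__shared__"


@dataclass
class EffectRegion:
    """A set of mask voxels carrying a planted adaptation contrast.

    Parameters
    ----------
    voxels : (K, 3) int array
        Lattice coordinates of the region (must lie inside the mask).
    effect_formats : sequence of str
        Formats whose adaptation contrast is expressed here.
    shared_across_formats : bool
        If True the multivariate pattern separating the conditions is the
        same in every listed format (format-independent code); otherwise an
        independent pattern is drawn per format.
    groups : sequence of str
        Age groups expressing the effect.
    effect_size : float
        RMS per-voxel condition contrast in units of ``noise_sd``.
    cross_participant_consistency : float in [0, 1]
        Fraction of pattern variance common across participants.
    """

    voxels: np.ndarray
    effect_formats: tuple
    groups: tuple
    effect_size: float
    shared_across_formats: bool = True
    cross_participant_consistency: float = 1.0

    def __post_init__(self):
        self.voxels = np.atleast_2d(np.asarray(self.voxels, dtype=int))
        self.effect_formats = tuple(self.effect_formats)
        self.groups = tuple(self.groups)
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 <= self.cross_participant_consistency <= 1.0:
            raise ValueError("cross_participant_consistency must be in [0, 1]")

    def pattern_keys(self) -> list:
        if self.shared_across_formats:
            return [_SHARED_KEY]
        return sorted(self.effect_formats)

    def key_for(self, fmt: str) -> str:
        return _SHARED_KEY if self.shared_across_formats else fmt


@dataclass
class SimulationConfig:
    """Full description of a synthetic study.

    Defaults mirror the emulated design: 2 mm isotropic voxels, TR 2 s,
    9.6 s blocks, ten blocks per condition per run, dots/digits in both age
    groups plus letters in the younger group. Grid size and group sizes are
    desk-scale knobs; the design constants are not.
    """

    grid_shape: tuple = (16, 16, 16)
    voxel_size_mm: float = 2.0
    tr_s: float = 2.0
    n_per_group: dict = field(default_factory=lambda: {"5yo": 12, "8yo": 12})
    formats_per_group: dict = field(
        default_factory=lambda: {"5yo": ("dots", "digits", "letters"), "8yo": ("dots", "digits")}
    )
    blocks_per_condition: int = 10
    block_duration_s: float = 9.6
    runs_per_participant: int = 1
    tail_s: float = 8.0  # rest after the last block so its sample window fits
    region_specs: list = field(default_factory=list)
    noise_sd: float = 1.0
    drift: float = 0.5  # per-voxel linear drift SD, signal units per 100 s
    motion_artifact_rate: float = 0.02
    mask_radius_voxels: float = None  # None -> inscribed ellipsoid mask
    mean_shift: float = 0.5  # suppression (mean) share of the condition contrast
    seed: int = 0

    def n_volumes_per_run(self) -> int:
        total_s = 3 * self.blocks_per_condition * self.block_duration_s + self.tail_s
        return int(math.ceil(total_s / self.tr_s))

    def make_grid(self) -> VolumeGrid:
        if self.mask_radius_voxels is not None:
            mask = ball_mask(self.grid_shape, self.mask_radius_voxels)
        else:
            mask = ellipsoid_mask(self.grid_shape, margin=1)
        return VolumeGrid(self.grid_shape, self.voxel_size_mm, mask)

    def validate(self, grid: VolumeGrid) -> None:
        if self.tr_s <= 0 or self.block_duration_s <= 0 or self.noise_sd <= 0:
            raise ValueError("tr_s, block_duration_s and noise_sd must be positive")
        if self.blocks_per_condition < 1 or self.runs_per_participant < 1:
            raise ValueError("need at least one block and one run")
        if not 0.0 <= self.motion_artifact_rate <= 1.0:
            raise ValueError("motion_artifact_rate must be a probability")
        # every task block's sample window (6 s delay + 5 TRs) must fit the run
        if self.tail_s + self.block_duration_s < 6.0 + 5 * self.tr_s:
            raise ValueError(
                "run too short after the last block: increase tail_s so the "
                "delayed sample window of the final block fits"
            )
        for i, region in enumerate(self.region_specs):
            vox = region.voxels
            if np.any(vox < 0) or np.any(vox >= np.asarray(self.grid_shape)):
                raise ValueError(f"region {i} extends outside the grid")
            if not grid.mask[vox[:, 0], vox[:, 1], vox[:, 2]].all():
                raise ValueError(f"region {i} extends outside the gray-matter mask")
            for g in region.groups:
                if g not in self.n_per_group:
                    raise ValueError(f"region {i} references unknown group {g!r}")


@dataclass
class GroundTruth:
    """What was planted where: regions, realized patterns and the seed chain."""

    regions: list  # serialized EffectRegion dicts
    shared_patterns: dict  # region index -> {pattern key -> list}
    participant_patterns: dict  # pid -> {"<region>/<key>" -> list}
    seed: int

    def region_mask(self, grid: VolumeGrid, region_index: int) -> np.ndarray:
        """Boolean masked-vector indicator of one region."""
        vox = np.asarray(self.regions[region_index]["voxels"], dtype=int)
        out = np.zeros(grid.n_voxels, dtype=bool)
        cols = grid.column_index[vox[:, 0], vox[:, 1], vox[:, 2]]
        out[cols[cols >= 0]] = True
        return out

    def to_dict(self) -> dict:
        return {
            "regions": self.regions,
            "shared_patterns": self.shared_patterns,
            "participant_patterns": self.participant_patterns,
            "seed": self.seed,
        }

    @staticmethod
    def from_dict(d: dict) -> "GroundTruth":
        return GroundTruth(d["regions"], d["shared_patterns"], d["participant_patterns"], d["seed"])


def make_condition_order(n_blocks_per_type: int, seed: int) -> list:
    """Pseudorandomized block order: ``n`` of each type, no identical neighbours.

    Builds the sequence left to right, drawing uniformly among the labels
    that still have blocks left, differ from the previous block, and leave a
    completable remainder (checked by exact memoized recursion over the small
    count/previous-label state space).
    """
    if n_blocks_per_type < 1:
        raise ValueError("need at least one block per type")
    labels = [ADAPTATION, NO_ADAPTATION, FIXATION]
    rng = np.random.default_rng(seed)

    memo = {}

    def completable(counts: tuple, prev: int) -> bool:
        if sum(counts) == 0:
            return True
        key = (counts, prev)
        if key not in memo:
            memo[key] = any(
                counts[j] > 0
                and j != prev
                and completable(tuple(c - (k == j) for k, c in enumerate(counts)), j)
                for j in range(3)
            )
        return memo[key]

    counts = [n_blocks_per_type] * 3
    seq = []
    prev = -1
    for _ in range(3 * n_blocks_per_type):
        feasible = [
            j
            for j in range(3)
            if counts[j] > 0
            and j != prev
            and completable(tuple(c - (k == j) for k, c in enumerate(counts)), j)
        ]
        if not feasible:
            raise ValueError("block order constraint is infeasible")
        pick = feasible[rng.integers(len(feasible))]
        seq.append(labels[pick])
        counts[pick] -= 1
        prev = pick
    return seq


def _block_weights(onsets, duration, n_volumes, tr_s, delay_s=6.0):
    """Delayed boxcar response per block, integrated over each TR.

    The response to a block at onset ``t`` occupies ``[t + delay, t + delay +
    duration)``; each volume's weight is the fraction of its TR covered.
    """
    t_start = np.arange(n_volumes) * tr_s
    t_end = t_start + tr_s
    w = np.zeros((len(onsets), n_volumes))
    for i, on in enumerate(onsets):
        lo, hi = on + delay_s, on + delay_s + duration
        overlap = np.minimum(t_end, hi) - np.maximum(t_start, lo)
        w[i] = np.clip(overlap, 0.0, None) / tr_s
    return w


def generate_dataset(config: SimulationConfig):
    """Generate a complete synthetic dataset.

    Returns
    -------
    participants : list of ParticipantData
    grid : VolumeGrid
    truth : GroundTruth
    """
    grid = config.make_grid()
    config.validate(grid)
    V = grid.n_voxels
    regions = config.region_specs

    # fixed seed-splitting: one stream for shared patterns, one per participant
    root = np.random.SeedSequence(config.seed)
    n_participants = sum(config.n_per_group[g] for g in sorted(config.n_per_group))
    streams = root.spawn(1 + n_participants)
    rng_patterns = np.random.default_rng(streams[0])

    region_cols = []
    shared_patterns = {}
    for ri, region in enumerate(regions):
        vox = region.voxels
        cols = grid.column_index[vox[:, 0], vox[:, 1], vox[:, 2]]
        region_cols.append(cols)
        shared_patterns[ri] = {
            key: rng_patterns.standard_normal(len(cols)) for key in region.pattern_keys()
        }

    # per-voxel RMS of (mu + pattern) is sqrt(1 + mu^2); normalize so that
    # effect_size is the RMS condition contrast in noise-SD units
    mu = config.mean_shift
    scale = config.noise_sd / math.sqrt(1.0 + mu**2)

    participants = []
    participant_patterns = {}
    pidx = 0
    for group in sorted(config.n_per_group):
        for _ in range(config.n_per_group[group]):
            rng = np.random.default_rng(streams[1 + pidx])
            pid = f"sub-{pidx + 1:02d}"
            iq = float(rng.normal(100.0, 15.0))

            # realized per-participant patterns for every region/format key
            patterns = {}
            for ri, region in enumerate(regions):
                c = region.cross_participant_consistency
                for key in region.pattern_keys():
                    idio = rng.standard_normal(len(region_cols[ri]))
                    patterns[f"{ri}/{key}"] = (
                        math.sqrt(c) * shared_patterns[ri][key] + math.sqrt(1.0 - c) * idio
                    )
            participant_patterns[pid] = {k: v.tolist() for k, v in patterns.items()}

            runs = {}
            for fmt in config.formats_per_group[group]:
                for run_idx in range(config.runs_per_participant):
                    runs[(fmt, run_idx)] = _generate_run(
                        config, grid, regions, region_cols, patterns, group, fmt, scale, rng
                    )
            participants.append(ParticipantData(pid, group, iq, runs))
            pidx += 1

    truth = GroundTruth(
        regions=[
            {
                "voxels": r.voxels.tolist(),
                "effect_formats": list(r.effect_formats),
                "shared_across_formats": r.shared_across_formats,
                "groups": list(r.groups),
                "effect_size": r.effect_size,
                "cross_participant_consistency": r.cross_participant_consistency,
            }
            for r in regions
        ],
        shared_patterns={
            ri: {k: v.tolist() for k, v in pats.items()} for ri, pats in shared_patterns.items()
        },
        participant_patterns=participant_patterns,
        seed=config.seed,
    )
    return participants, grid, truth


def _generate_run(config, grid, regions, region_cols, patterns, group, fmt, scale, rng):
    """One run's time series, events and motion for one participant/format."""
    V = grid.n_voxels
    n = config.blocks_per_condition
    T = config.n_volumes_per_run()
    order = make_condition_order(n, int(rng.integers(2**31)))
    onsets = np.arange(3 * n) * config.block_duration_s

    ts = rng.standard_normal((T, V)) * config.noise_sd
    # slow per-voxel linear drift
    slopes = rng.normal(0.0, config.drift, V) / 100.0
    ts += np.outer(np.arange(T) * config.tr_s, slopes)

    # condition contrast: no-adaptation up, adaptation down (repetition suppression)
    weights = _block_weights(onsets, config.block_duration_s, T, config.tr_s)
    signs = np.array(
        [0.5 if c == NO_ADAPTATION else (-0.5 if c == ADAPTATION else 0.0) for c in order]
    )
    contrast_tc = signs @ weights  # length T
    mu = config.mean_shift
    for ri, region in enumerate(regions):
        if group not in region.groups or fmt not in region.effect_formats:
            continue
        w = patterns[f"{ri}/{region.key_for(fmt)}"]
        delta = region.effect_size * scale * (mu + w)
        ts[:, region_cols[ri]] += np.outer(contrast_tc, delta)

    # motion: smooth random walk with spikes at artifact volumes
    motion = np.cumsum(rng.normal(0.0, 0.02, (T, 6)), axis=0)
    artifact = rng.random(T) < config.motion_artifact_rate
    artifact[0] = False
    motion[artifact, 0] += 3.0  # single-volume translation spike (> 2 mm criterion)
    ts[artifact] += 1.5 * config.noise_sd  # global intensity spike

    events = pd.DataFrame(
        {"onset": onsets, "duration": config.block_duration_s, "trial_type": order}
    )
    return RunData(timeseries=ts, events=events, motion=motion, tr_s=config.tr_s)
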