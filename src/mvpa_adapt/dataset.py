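"""In-memory containers for participants, runs and classification samples.

Time series are stored masked: each run is a ``T x V`` matrix whose columns
follow ``VolumeGrid.mask_coords`` order. Block-averaged classification
samples live in a :class:`SampleSet`, one row per task block.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ADAPTATION = "adaptation"
NO_ADAPTATION = "no-adaptation"
FIXATION = "fixation"
TASK_CONDITIONS = (ADAPTATION, NO_ADAPTATION)


@dataclass
class RunData:
    """One functional run: masked time series, block events and motion traces."""

    timeseries: np.ndarray  # T x V, V = mask voxel count
    events: pd.DataFrame  # columns: onset, duration, trial_type
    motion: np.ndarray  # T x 6: x, y, z translations (mm); roll, pitch, yaw (deg)
    tr_s: float = 2.0

    @property
    def n_volumes(self) -> int:
        return self.timeseries.shape[0]


@dataclass
class ParticipantData:
    """All runs of one participant, with group membership and IQ covariate."""

    participant_id: str
    group: str
    iq: float
    runs: dict = field(default_factory=dict)  # (format, run_index) -> RunData

    @property
    def formats(self) -> list:
        return sorted({fmt for fmt, _ in self.runs})

    def runs_of(self, fmt: str) -> list:
        return [self.runs[key] for key in sorted(self.runs) if key[0] == fmt]


@dataclass
class SampleSet:
    """Block-averaged feature vectors: the classification samples.

    One row per task block (fixation never becomes a sample); columns are
    mask voxels. Label vectors run parallel to the rows.
    """

    features: np.ndarray  # S x V
    condition: np.ndarray  # of {adaptation, no-adaptation}
    participant_ids: np.ndarray
    formats: np.ndarray
    run_indices: np.ndarray

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=float)
        self.condition = np.asarray(self.condition)
        self.participant_ids = np.asarray(self.participant_ids)
        self.formats = np.asarray(self.formats)
        self.run_indices = np.asarray(self.run_indices, dtype=int)
        n = len(self.features)
        for v in (self.condition, self.participant_ids, self.formats, self.run_indices):
            if len(v) != n:
                raise ValueError("label vectors must match the number of samples")
        if set(np.unique(self.condition)) - set(TASK_CONDITIONS):
            raise ValueError("samples may only carry task conditions")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    def rows(self, participant=None, fmt=None, exclude_participant=None) -> np.ndarray:
        """Boolean row selector by participant and/or format."""
        keep = np.ones(self.n_samples, dtype=bool)
        if participant is not None:
            keep &= self.participant_ids == participant
        if exclude_participant is not None:
            keep &= self.participant_ids != exclude_participant
        if fmt is not None:
            keep &= self.formats == fmt
        return keep

    def subset(self, rows: np.ndarray) -> "SampleSet":
        return SampleSet(
            self.features[rows],
            self.condition[rows],
            self.participant_ids[rows],
            self.formats[rows],
            self.run_indices[rows],
        )

    @staticmethod
    def concat(parts: list) -> "SampleSet":
        parts = [p for p in parts if p.n_samples > 0]
        if not parts:
            raise ValueError("nothing to concatenate")
        return SampleSet(
            np.vstack([p.features for p in parts]),
            np.concatenate([p.condition for p in parts]),
            np.concatenate([p.participant_ids for p in parts]),
            np.concatenate([p.formats for p in parts]),
            np.concatenate([p.run_indices for p in parts]),
        )

    def to_frame(self) -> pd.DataFrame:
        """Label sidecar (no features) as a DataFrame."""
        return pd.DataFrame(
            {
                "participant_id": self.participant_ids,
                "format": self.formats,
                "run": self.run_indices,
                "condition": self.condition,
            }
        )
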