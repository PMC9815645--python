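"""Whole-brain cross-participant searchlight decoding.

For every gray-matter voxel, the block-averaged samples of all voxels within
a sphere (default radius 5 voxels, i.e. 10 mm at 2 mm isotropic) are the
features of an SVM with RBF kernel and C = 1 that classifies adaptation vs
no-adaptation blocks. Classifiers are always trained and tested on different
participants, so above-chance accuracy reflects spatially consistent coding
across brains. Three schemes are supported:

``within_loocv``
    Leave-one-participant-out within a group: train on the other N-1
    participants' samples of one format, test the left-out participant's
    samples of the same format. ``cv=("kfold", k)`` replaces LOOCV with a
    participant-level k-fold split.
``within_crossgroup``
    Train once on all participants of one group, test every participant of
    the other group, same format.
``between_loocv``
    As ``within_loocv`` but the left-out participant is tested on a
    different format; none of that participant's samples (either format)
    enter training.

The RBF bandwidth follows the ``gamma='scale'`` convention,
``1 / (n_features * var(features))``, the scikit-learn default the original
analysis stack would have used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import NO_ADAPTATION, SampleSet
from .grid import VolumeGrid

CHANCE_LEVEL = 0.5

# Direct libsvm calls skip per-call estimator validation (~2x faster at
# searchlight scale); fall back to the public SVC API if unavailable.
try:  # pragma: no cover - exercised implicitly
    from sklearn.svm import _libsvm as _fast_svm

    _fast_svm.set_verbosity_wrap(0)
except Exception:  # pragma: no cover
    _fast_svm = None

from sklearn.svm import SVC


@dataclass
class SearchlightSpec:
    """Sphere geometry for the searchlight scan."""

    radius: float = 5.0
    radius_unit: str = "voxels"  # or "mm"
    use_fast_svm: bool = True

    def radius_in_voxels(self, grid: VolumeGrid) -> float:
        if self.radius_unit == "voxels":
            return self.radius
        if self.radius_unit == "mm":
            return self.radius / float(grid.voxel_size_mm[0])
        raise ValueError("radius_unit must be 'voxels' or 'mm'")


@dataclass
class DecodingScheme:
    """One decoding analysis: who trains, who tests, on which formats."""

    name: str  # within_loocv | within_crossgroup | between_loocv
    train_format: str
    test_format: str
    train_group: str
    test_group: str
    cv: tuple = ("loocv",)  # ("loocv",) or ("kfold", k)
    cv_seed: int = 0

    def __post_init__(self):
        if self.name == "within_loocv":
            if self.train_format != self.test_format or self.train_group != self.test_group:
                raise ValueError("within_loocv requires equal formats and groups")
        elif self.name == "between_loocv":
            if self.train_format == self.test_format:
                raise ValueError("between_loocv requires different formats")
            if self.train_group != self.test_group:
                raise ValueError("between_loocv operates within one group")
        elif self.name == "within_crossgroup":
            if self.train_format != self.test_format:
                raise ValueError("within_crossgroup requires equal formats")
            if self.train_group == self.test_group:
                raise ValueError("within_crossgroup requires different groups")
            if self.cv != ("loocv",):
                raise ValueError("within_crossgroup takes no cross-validation")
        else:
            raise ValueError(f"unknown scheme {self.name!r}")

    def label(self) -> str:
        fmt = (
            self.train_format
            if self.train_format == self.test_format
            else f"{self.train_format}2{self.test_format}"
        )
        grp = (
            self.train_group
            if self.train_group == self.test_group
            else f"{self.train_group}2{self.test_group}"
        )
        cv = "LOOCV" if self.cv[0] == "loocv" else f"{self.cv[1]}fold"
        kind = {"within_loocv": cv, "within_crossgroup": "CrossGroup", "between_loocv": cv}[
            self.name
        ]
        return f"{kind}_{grp}_{fmt}"


@dataclass
class AccuracyMap:
    """Decoding accuracy at every sphere center for one test participant."""

    participant_id: str
    group: str
    scheme: str
    train_format: str
    test_format: str
    values: np.ndarray  # (V,) in [0, 1]; chance = 0.5
    chance: float = CHANCE_LEVEL


def maps_to_matrix(maps: list) -> np.ndarray:
    """Stack per-participant accuracy maps into a (P, V) matrix."""
    return np.vstack([m.values for m in maps])


def _fit_predict(train_X, train_y, test_X, fast=True):
    """Train SVM-RBF (C=1, gamma='scale') and predict test labels (0/1 floats)."""
    var = train_X.var()
    if var <= 0:
        # featureless sphere: predict the majority training class
        maj = float(np.round(train_y.mean()))
        return np.full(len(test_X), maj)
    gamma = 1.0 / (train_X.shape[1] * var)
    if fast and _fast_svm is not None:
        model = _fast_svm.fit(train_X, train_y, svm_type=0, kernel="rbf", C=1.0, gamma=gamma)
        return _fast_svm.predict(test_X, *model[:7], svm_type=0, kernel="rbf", gamma=gamma)
    clf = SVC(C=1.0, kernel="rbf", gamma=gamma).fit(train_X, train_y)
    return clf.predict(test_X)


def fit_and_score(train: SampleSet, test: SampleSet, sphere_cols: np.ndarray, fast=True) -> float:
    """Accuracy of the sphere classifier trained on ``train``, scored on ``test``."""
    ytr = np.unique(train.condition)
    if len(ytr) < 2:
        raise ValueError("training set must contain both conditions")
    train_y = (train.condition == NO_ADAPTATION).astype(float)
    test_y = (test.condition == NO_ADAPTATION).astype(float)
    Xtr = np.ascontiguousarray(train.features[:, sphere_cols])
    Xte = np.ascontiguousarray(test.features[:, sphere_cols])
    pred = _fit_predict(Xtr, train_y, Xte, fast=fast)
    return float(np.mean(pred == test_y))


def _score_fold(features, train_rows, test_blocks, y, members, fast):
    """Accuracy over all sphere centers for one train/test fold.

    ``test_blocks`` is a list of (participant_id, row-index array); the model
    at each center is fit once and scored on every block, so the
    within_crossgroup scheme costs a single fit per center.
    """
    Ftr = np.ascontiguousarray(features[train_rows])
    ytr = np.ascontiguousarray(y[train_rows])
    test_idx = np.concatenate([idx for _, idx in test_blocks])
    Fte = np.ascontiguousarray(features[test_idx])
    yte = y[test_idx]
    splits = np.cumsum([len(idx) for _, idx in test_blocks])[:-1]
    n_centers = len(members)
    out = {pid: np.empty(n_centers) for pid, _ in test_blocks}
    for ci, cols in enumerate(members):
        Xtr = np.ascontiguousarray(Ftr[:, cols])
        Xte = np.ascontiguousarray(Fte[:, cols])
        pred = _fit_predict(Xtr, ytr, Xte, fast=fast)
        correct = pred == yte
        for (pid, _), chunk in zip(test_blocks, np.split(correct, splits)):
            out[pid][ci] = chunk.mean()
    return out


def run_scheme(
    samples: SampleSet,
    scheme: DecodingScheme,
    spec: SearchlightSpec,
    grid: VolumeGrid,
    groups: dict,
) -> list:
    """Compute one accuracy map per test participant under ``scheme``.

    Parameters
    ----------
    samples : SampleSet
        Pooled preprocessed samples of all participants.
    groups : mapping participant_id -> group label
    """
    members = grid.sphere_columns(spec.radius_in_voxels(grid))
    y = (samples.condition == NO_ADAPTATION).astype(float)
    features = samples.features
    pid_arr = samples.participant_ids
    fast = spec.use_fast_svm

    def group_pids(g):
        pids = sorted({p for p in np.unique(pid_arr) if groups[str(p)] == g})
        return pids

    results = {}
    if scheme.name == "within_crossgroup":
        train_rows = np.isin(pid_arr, group_pids(scheme.train_group)) & (
            samples.formats == scheme.train_format
        )
        test_pids = group_pids(scheme.test_group)
        blocks = [
            (p, np.flatnonzero((pid_arr == p) & (samples.formats == scheme.test_format)))
            for p in test_pids
        ]
        blocks = [(p, idx) for p, idx in blocks if len(idx)]
        if train_rows.sum() == 0 or not blocks:
            raise ValueError("scheme/format mismatch: no training or test samples")
        results.update(_score_fold(features, train_rows, blocks, y, members, fast))
    else:
        pids = group_pids(scheme.train_group)
        if len(pids) < 2:
            raise ValueError("need at least two participants for cross-validation")
        folds = _make_folds(pids, scheme)
        for held_out in folds:
            train_rows = (
                np.isin(pid_arr, pids)
                & ~np.isin(pid_arr, held_out)
                & (samples.formats == scheme.train_format)
            )
            blocks = [
                (p, np.flatnonzero((pid_arr == p) & (samples.formats == scheme.test_format)))
                for p in held_out
            ]
            blocks = [(p, idx) for p, idx in blocks if len(idx)]
            if train_rows.sum() == 0 or not blocks:
                raise ValueError("scheme/format mismatch: no training or test samples")
            results.update(_score_fold(features, train_rows, blocks, y, members, fast))

    return [
        AccuracyMap(
            participant_id=str(p),
            group=groups[str(p)],
            scheme=scheme.name,
            train_format=scheme.train_format,
            test_format=scheme.test_format,
            values=vals,
        )
        for p, vals in sorted(results.items())
    ]


def _make_folds(pids: list, scheme: DecodingScheme) -> list:
    """Held-out participant groups: singletons for LOOCV, k near-equal folds else."""
    if scheme.cv[0] == "loocv":
        return [[p] for p in pids]
    if scheme.cv[0] == "kfold":
        k = int(scheme.cv[1])
        if not 2 <= k <= len(pids):
            raise ValueError("k must be between 2 and the number of participants")
        rng = np.random.default_rng(scheme.cv_seed)
        order = list(rng.permutation(pids))
        return [order[i::k] for i in range(k)]
    raise ValueError(f"unknown cv {scheme.cv!r}")
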