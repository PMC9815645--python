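"""Reading and writing datasets, samples and statistic maps.

Datasets are laid out BIDS-like: one 4-D NIfTI per participant/format/run
(``sub-XX_task-<format>_run-<R>_bold.nii``), an events TSV and a motion TSV
per run, a 3-D gray-matter mask, a participants TSV and (for synthetic data)
a ground-truth JSON. Output defaults to uncompressed ``.nii`` so repeated
runs with the same seed are byte-identical (gzip embeds timestamps);
``compress=True`` switches to ``.nii.gz``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .dataset import ParticipantData, RunData, SampleSet
from .grid import VolumeGrid
from .simulate import GroundTruth

_BOLD_RE = re.compile(r"(?P<pid>sub-[^_]+)_task-(?P<fmt>[^_]+)_run-(?P<run>\d+)_bold\.nii(\.gz)?$")


def _nii_name(base: str, compress: bool) -> str:
    return base + (".nii.gz" if compress else ".nii")


def write_map(values: np.ndarray, grid: VolumeGrid, path, fill: float = 0.0) -> Path:
    """Write a masked vector as a 3-D NIfTI volume."""
    img = nib.Nifti1Image(grid.embed(values, fill=fill), grid.affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def read_map(path, grid: VolumeGrid) -> np.ndarray:
    """Read a 3-D NIfTI volume back into masked-vector form."""
    img = nib.load(str(path))
    return grid.extract(np.asarray(img.dataobj, dtype=float))


def write_mask(grid: VolumeGrid, path) -> Path:
    img = nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_grid(mask_path, voxel_size_mm=None) -> VolumeGrid:
    img = nib.load(str(mask_path))
    mask = np.asarray(img.dataobj) > 0
    if voxel_size_mm is None:
        voxel_size_mm = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGrid(mask.shape, voxel_size_mm, mask, affine=np.asarray(img.affine))


def save_dataset(participants, grid: VolumeGrid, truth, out_dir, compress: bool = False) -> Path:
    """Write a dataset in the BIDS-like layout described in the module docstring."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_mask(grid, out / _nii_name("mask", compress))

    rows = []
    tr_s = None
    for p in participants:
        pdir = out / p.participant_id
        pdir.mkdir(exist_ok=True)
        for (fmt, run_idx), run in sorted(p.runs.items()):
            tr_s = run.tr_s
            base = f"{p.participant_id}_task-{fmt}_run-{run_idx + 1}"
            T = run.n_volumes
            vol4d = np.zeros(grid.shape + (T,))
            vol4d[grid.mask, :] = run.timeseries.T
            nib.save(
                nib.Nifti1Image(vol4d, grid.affine), str(pdir / _nii_name(base + "_bold", compress))
            )
            run.events.to_csv(pdir / f"{base}_events.tsv", sep="\t", index=False)
            pd.DataFrame(
                run.motion,
                columns=["trans_x", "trans_y", "trans_z", "rot_roll", "rot_pitch", "rot_yaw"],
            ).to_csv(pdir / f"{base}_motion.tsv", sep="\t", index=False)
        rows.append({"participant_id": p.participant_id, "group": p.group, "iq": p.iq})
    pd.DataFrame(rows).to_csv(out / "participants.tsv", sep="\t", index=False)
    (out / "dataset_description.json").write_text(
        json.dumps({"tr_s": tr_s, "voxel_size_mm": grid.voxel_size_mm}, indent=2)
    )
    if truth is not None:
        (out / "ground_truth.json").write_text(json.dumps(truth.to_dict(), indent=2))
    return out


def load_dataset(in_dir):
    """Load a dataset written by :func:`save_dataset` (or any matching layout).

    Returns ``(participants, grid, truth_or_None)``.
    """
    root = Path(in_dir)
    masks = sorted(root.glob("mask.nii*"))
    if not masks:
        raise FileNotFoundError(f"no mask.nii[.gz] under {root}")
    desc = {}
    desc_path = root / "dataset_description.json"
    if desc_path.exists():
        desc = json.loads(desc_path.read_text())
    grid = load_grid(masks[0], voxel_size_mm=desc.get("voxel_size_mm"))
    tr_s = float(desc.get("tr_s", 2.0))

    table = pd.read_csv(root / "participants.tsv", sep="\t")
    participants = []
    for _, row in table.iterrows():
        pid = row["participant_id"]
        runs = {}
        for bold in sorted((root / pid).glob(f"{pid}_task-*_bold.nii*")):
            m = _BOLD_RE.search(bold.name)
            if not m:
                continue
            fmt, run_idx = m.group("fmt"), int(m.group("run")) - 1
            vol4d = np.asarray(nib.load(str(bold)).dataobj, dtype=float)
            ts = vol4d[grid.mask, :].T
            base = f"{pid}_task-{fmt}_run-{run_idx + 1}"
            events = pd.read_csv(root / pid / f"{base}_events.tsv", sep="\t")
            motion = pd.read_csv(root / pid / f"{base}_motion.tsv", sep="\t").to_numpy()
            runs[(fmt, run_idx)] = RunData(ts, events, motion, tr_s=tr_s)
        participants.append(ParticipantData(pid, str(row["group"]), float(row["iq"]), runs))

    truth = None
    gt_path = root / "ground_truth.json"
    if gt_path.exists():
        truth = GroundTruth.from_dict(json.loads(gt_path.read_text()))
    return participants, grid, truth


def save_samples(samples: SampleSet, grid: VolumeGrid, path) -> Path:
    """Persist a sample set plus its grid in one portable .npz container."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(
        path,
        features=samples.features,
        condition=samples.condition.astype(str),
        participant_ids=samples.participant_ids.astype(str),
        formats=samples.formats.astype(str),
        run_indices=samples.run_indices,
        mask=grid.mask,
        affine=grid.affine,
        voxel_size_mm=np.asarray(grid.voxel_size_mm),
    )
    return path


def load_samples(path):
    """Inverse of :func:`save_samples`; returns ``(samples, grid)``."""
    z = np.load(path, allow_pickle=False)
    grid = VolumeGrid(
        z["mask"].shape, tuple(z["voxel_size_mm"]), z["mask"].astype(bool), affine=z["affine"]
    )
    samples = SampleSet(
        z["features"],
        z["condition"],
        z["participant_ids"],
        z["formats"],
        z["run_indices"],
    )
    return samples, grid


def accuracy_map_filename(scheme_label: str, participant_id: str, compress: bool = False) -> str:
    """Naming convention for per-participant raw accuracy maps."""
    return _nii_name(f"RawDecAcc_{scheme_label}_{participant_id}", compress)


def write_cluster_table(report, path, atlas=None) -> Path:
    """One TSV row per cluster (header-only file when there are none)."""
    df = report.to_dataframe()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def apply_atlas_labels(report, grid: VolumeGrid, atlas_path, labels_path) -> None:
    """Resolve each cluster's peak-voxel label from an integer atlas.

    ``atlas_path`` is any integer-labelled NIfTI on the same grid;
    ``labels_path`` a TSV with columns ``index`` and ``name``.
    """
    atlas = np.asarray(nib.load(str(atlas_path)).dataobj).astype(int)
    if atlas.shape != grid.shape:
        raise ValueError("atlas is not on the analysis grid")
    names = pd.read_csv(labels_path, sep="\t").set_index("index")["name"].to_dict()
    for c in report.clusters:
        c.label = names.get(int(atlas[c.peak_voxel]), "")
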