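"""Declarative analysis plans: the full decoding/inference battery.

An :class:`AnalysisPlan` is an ordered list of entries, each naming a
statistical test over one or two sets of searchlight accuracy maps. The
default battery reproduces the standard analysis suite for a two-group,
multi-format adaptation study: within-format decoding per group and format,
cross-group transfer in both directions with a conjunction, between-format
decoding in both directions with a conjunction per group, direct group
comparisons, letter-format specificity controls, covariate-residualized
reruns, a k-fold cross-validation variant and an alternative voxel-threshold
variant. Plans are serializable, seeded from a single master seed and
re-runnable to byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .grid import ball_region
from .inference import (
    PermutationSpec,
    conjunction,
    one_sample_permutation,
    residualize_accuracy,
    two_sample_permutation,
)
from .preprocess import MOTION_COLUMNS, build_samples
from .searchlight import AccuracyMap, DecodingScheme, SearchlightSpec, run_scheme
from .simulate import EffectRegion, SimulationConfig


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent data (CLI exit code 3)."""


@dataclass
class PlanEntry:
    """One test of the battery.

    ``kind`` is ``one_sample`` (schemes_a holds one scheme), ``conjunction``
    (schemes_a holds the two directions) or ``two_sample`` (schemes_a vs
    schemes_b; several schemes on a side are averaged per participant, e.g.
    the two between-format directions).
    """

    name: str
    kind: str
    schemes_a: list
    schemes_b: list = None
    residualize: bool = False
    overrides: dict = field(default_factory=dict)


@dataclass
class AnalysisPlan:
    entries: list
    searchlight: SearchlightSpec = field(default_factory=SearchlightSpec)
    inference: PermutationSpec = field(default_factory=PermutationSpec)
    seed: int = 0


def _within(g, f, cv=("loocv",), cv_seed=0):
    return DecodingScheme("within_loocv", f, f, g, g, cv=cv, cv_seed=cv_seed)


def _crossgroup(g_train, g_test, f):
    return DecodingScheme("within_crossgroup", f, f, g_train, g_test)


def _between(g, f_train, f_test, cv=("loocv",), cv_seed=0):
    return DecodingScheme("between_loocv", f_train, f_test, g, g, cv=cv, cv_seed=cv_seed)


def default_battery(
    formats_per_group: dict,
    residualized: bool = True,
    kfold: int = 10,
    alt_voxel_p: float = 0.001,
) -> list:
    """The standard analysis battery for the given group/format layout.

    Letter controls are added automatically for groups that have a
    ``letters`` format; set ``kfold``/``alt_voxel_p``/``residualized`` to
    None/False to skip the robustness reruns.
    """
    groups = sorted(formats_per_group)
    entries = []
    core_formats = ["dots", "digits"]

    for g in groups:
        for f in formats_per_group[g]:
            entries.append(PlanEntry(f"within_{g}_{f}", "one_sample", [_within(g, f)]))
    if len(groups) == 2:
        a, b = groups
        shared = [f for f in formats_per_group[a] if f in formats_per_group[b]]
        for f in shared:
            entries.append(
                PlanEntry(
                    f"crossgroup_conj_{f}",
                    "conjunction",
                    [_crossgroup(a, b, f), _crossgroup(b, a, f)],
                )
            )
            entries.append(
                PlanEntry(
                    f"groupdiff_within_{f}_{b}_gt_{a}",
                    "two_sample",
                    [_within(b, f)],
                    [_within(a, f)],
                )
            )
            entries.append(
                PlanEntry(
                    f"groupdiff_within_{f}_{a}_gt_{b}",
                    "two_sample",
                    [_within(a, f)],
                    [_within(b, f)],
                )
            )
    for g in groups:
        fmts = [f for f in core_formats if f in formats_per_group[g]]
        if len(fmts) == 2:
            f1, f2 = fmts
            entries.append(
                PlanEntry(
                    f"between_conj_{g}_{f1}_{f2}",
                    "conjunction",
                    [_between(g, f1, f2), _between(g, f2, f1)],
                )
            )
    if len(groups) == 2:
        a, b = groups
        if all(set(core_formats) <= set(formats_per_group[g]) for g in groups):
            entries.append(
                PlanEntry(
                    "groupdiff_between_" + a + "_gt_" + b,
                    "two_sample",
                    [_between(a, "dots", "digits"), _between(a, "digits", "dots")],
                    [_between(b, "dots", "digits"), _between(b, "digits", "dots")],
                )
            )
    # letter specificity controls
    for g in groups:
        if "letters" in formats_per_group[g]:
            for f in core_formats:
                if f in formats_per_group[g]:
                    entries.append(
                        PlanEntry(
                            f"letters_conj_{g}_{f}",
                            "conjunction",
                            [_between(g, f, "letters"), _between(g, "letters", f)],
                        )
                    )
    # robustness reruns on the headline between-format conjunctions
    main_conjs = [e for e in entries if e.kind == "conjunction" and e.name.startswith("between")]
    if residualized:
        for e in list(entries):
            if e.kind in ("one_sample", "conjunction"):
                entries.append(
                    PlanEntry(
                        e.name + "_residualized", e.kind, e.schemes_a, e.schemes_b, residualize=True
                    )
                )
    if kfold:
        for e in main_conjs:
            schemes = [dataclasses.replace(s, cv=("kfold", kfold)) for s in e.schemes_a]
            entries.append(PlanEntry(e.name + f"_{kfold}fold", e.kind, schemes))
    if alt_voxel_p:
        for e in main_conjs:
            entries.append(
                PlanEntry(
                    e.name + "_voxelp001",
                    e.kind,
                    e.schemes_a,
                    e.schemes_b,
                    overrides={"voxel_p_threshold": alt_voxel_p},
                )
            )
    return entries


def _entry_seed(master: int, index: int, extra: int = 0) -> int:
    return int(np.random.SeedSequence([master, index, extra]).generate_state(1)[0] & 0x7FFFFFFF)


def _average_maps(map_lists):
    """Average accuracy maps across schemes per participant (matched by id)."""
    if len(map_lists) == 1:
        return map_lists[0]
    by_pid = {}
    for maps in map_lists:
        for m in maps:
            by_pid.setdefault(m.participant_id, []).append(m)
    out = []
    for pid in sorted(by_pid):
        ms = by_pid[pid]
        avg = dataclasses.replace(ms[0], values=np.mean([m.values for m in ms], axis=0))
        out.append(avg)
    return out


def run_plan(participants, grid, plan: AnalysisPlan, out_dir, make_figures: bool = True) -> dict:
    """Execute a plan end to end; returns a summary dict (also written to disk).

    The artifact tree holds raw per-participant accuracy maps, unthresholded
    -log10(p) maps, cluster tables, provenance and a markdown summary.
    Identical inputs and master seed reproduce every output byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    samples, table, qc = build_samples(participants)
    groups = table["group"].to_dict()
    covariates = table[list(MOTION_COLUMNS) + ["iq"]]

    log_lines = [f"participants retained: {len(table)}"]
    for pid, reason in qc.excluded.items():
        log_lines.append(f"excluded {pid}: {reason}")

    maps_cache = {}

    def get_maps(scheme):
        key = scheme.label()
        if key not in maps_cache:
            maps = run_scheme(samples, scheme, plan.searchlight, grid, groups)
            maps_cache[key] = maps
            mdir = out / "accuracy_maps"
            for m in maps:
                mio.write_map(m.values, grid, mdir / mio.accuracy_map_filename(key, m.participant_id))
            (mdir / f"{key}_meta.json").write_text(
                json.dumps(
                    {
                        "scheme": scheme.name,
                        "train_format": scheme.train_format,
                        "test_format": scheme.test_format,
                        "train_group": scheme.train_group,
                        "test_group": scheme.test_group,
                        "cv": list(scheme.cv),
                        "radius": plan.searchlight.radius,
                        "radius_unit": plan.searchlight.radius_unit,
                        "gamma": "scale (1 / (n_features * var))",
                        "n_maps": len(maps),
                    },
                    indent=2,
                )
            )
        return maps_cache[key]

    def prep(map_lists, residualize):
        maps = _average_maps(map_lists)
        if residualize:
            maps = residualize_accuracy(maps, covariates)
        return maps

    summary_entries = []
    for i, entry in enumerate(plan.entries):
        spec = dataclasses.replace(
            plan.inference, seed=_entry_seed(plan.seed, i), **entry.overrides
        )
        try:
            if entry.kind == "one_sample":
                maps = prep([get_maps(s) for s in entry.schemes_a], entry.residualize)
                result = one_sample_permutation(maps, spec, grid)
                mean_map = np.mean([m.values for m in maps], axis=0)
            elif entry.kind == "two_sample":
                maps_a = prep([get_maps(s) for s in entry.schemes_a], entry.residualize)
                maps_b = prep([get_maps(s) for s in entry.schemes_b], entry.residualize)
                result = two_sample_permutation(maps_a, maps_b, spec, grid)
                mean_map = np.mean([m.values for m in maps_a], axis=0)
            elif entry.kind == "conjunction":
                directions = []
                for d, scheme in enumerate(entry.schemes_a):
                    dspec = dataclasses.replace(
                        spec, seed=_entry_seed(plan.seed, i, d + 1), keep_null=True
                    )
                    maps = prep([get_maps(scheme)], entry.residualize)
                    directions.append(one_sample_permutation(maps, dspec, grid))
                result = conjunction(directions[0], directions[1], spec, grid)
                mean_map = None
            else:
                raise ConfigError(f"unknown entry kind {entry.kind!r}")
        except ValueError as exc:
            log_lines.append(f"skipped {entry.name}: {exc}")
            warnings.warn(f"skipped plan entry {entry.name}: {exc}")
            continue

        idir = out / "inference"
        logp = -np.log10(np.maximum(result.p, 1.0 / result.n_permutations))
        mio.write_map(logp, grid, idir / f"{entry.name}_LogPval.nii")
        mio.write_cluster_table(result.clusters, idir / f"{entry.name}_clusters.tsv")
        sig = result.clusters.significant()
        summary_entries.append(
            {
                "entry": entry.name,
                "kind": entry.kind,
                "n_permutations": result.n_permutations,
                "mode": result.mode,
                "n_clusters": len(result.clusters.clusters),
                "n_significant": len(sig),
                "largest_significant_size": max((c.size for c in sig), default=0),
            }
        )
        if make_figures and mean_map is not None:
            _histogram_figure(mean_map, out / "figures" / f"{entry.name}_hist.png", entry.name)

    provenance = {
        "seed": plan.seed,
        "searchlight": dataclasses.asdict(plan.searchlight),
        "inference": dataclasses.asdict(plan.inference),
        "entries": [
            {
                "name": e.name,
                "kind": e.kind,
                "residualize": e.residualize,
                "overrides": e.overrides,
                "schemes_a": [dataclasses.asdict(s) for s in e.schemes_a],
                "schemes_b": [dataclasses.asdict(s) for s in e.schemes_b] if e.schemes_b else None,
            }
            for e in plan.entries
        ],
        "excluded_participants": qc.excluded,
        "dropped_samples": qc.dropped_samples,
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=list))

    lines = ["# Analysis summary", "", "## Log", ""]
    lines += [f"- {line}" for line in log_lines]
    lines += ["", "## Results", ""]
    if summary_entries:
        df = pd.DataFrame(summary_entries)
        lines.append(df.to_markdown(index=False))
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    return {"entries": summary_entries, "log": log_lines, "out_dir": str(out)}


def _histogram_figure(mean_map, path, title):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(mean_map, bins=30, color="steelblue")
    ax.axvline(0.5, color="k", ls="--", lw=1)
    ax.set_xlabel("mean decoding accuracy")
    ax.set_ylabel("voxels")
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


# ---------------------------------------------------------------------------
# configuration parsing (YAML dicts -> dataclasses)


def simulation_config_from_dict(cfg: dict) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a parsed YAML mapping.

    Effect regions are given either as explicit ``voxels`` lists or as
    ``center``/``radius`` balls.
    """
    cfg = dict(cfg)
    regions = []
    shape = tuple(cfg.get("grid_shape", (16, 16, 16)))
    for spec in cfg.pop("region_specs", []) or []:
        spec = dict(spec)
        if "voxels" in spec:
            voxels = np.asarray(spec.pop("voxels"), dtype=int)
        else:
            voxels = ball_region(spec.pop("center"), spec.pop("radius"), shape)
        regions.append(
            EffectRegion(
                voxels=voxels,
                effect_formats=tuple(spec["effect_formats"]),
                groups=tuple(spec["groups"]),
                effect_size=float(spec["effect_size"]),
                shared_across_formats=bool(spec.get("shared_across_formats", True)),
                cross_participant_consistency=float(
                    spec.get("cross_participant_consistency", 1.0)
                ),
            )
        )
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(cfg) - known
    if unknown:
        raise ConfigError(f"unknown simulation keys: {sorted(unknown)}")
    if "grid_shape" in cfg:
        cfg["grid_shape"] = tuple(cfg["grid_shape"])
    if "formats_per_group" in cfg:
        cfg["formats_per_group"] = {g: tuple(v) for g, v in cfg["formats_per_group"].items()}
    return SimulationConfig(region_specs=regions, **cfg)


def plan_from_dict(cfg: dict, formats_per_group: dict) -> AnalysisPlan:
    """Build an :class:`AnalysisPlan` (default battery) from a YAML mapping."""
    sl = SearchlightSpec(**cfg.get("searchlight", {}))
    inf_cfg = dict(cfg.get("inference", {}))
    if inf_cfg.pop("fast", False):
        inf_cfg.setdefault("n_permutations", 1000)
    inf = PermutationSpec(**inf_cfg)
    battery_cfg = cfg.get("battery", {})
    entries = default_battery(
        formats_per_group,
        residualized=battery_cfg.get("residualized", True),
        kfold=battery_cfg.get("kfold", 10),
        alt_voxel_p=battery_cfg.get("alt_voxel_p", 0.001),
    )
    return AnalysisPlan(entries=entries, searchlight=sl, inference=inf, seed=int(cfg.get("seed", 0)))
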