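"""Group-level nonparametric inference on accuracy maps.

The central test is a one-sample sign-permutation test: per participant the
chance level (0.5) is subtracted from the accuracy map and each permutation
flips the sign of each participant's whole map independently (spatially
coherent flips). Voxel-wise p is the fraction of permuted mean maps at least
as large as the observed mean (one-sided, the identity permutation counted,
so p >= 1/n_permutations). Cluster-wise inference thresholds the voxel p map
(default p < 0.005), forms connected components (default 26-connectivity)
and compares each observed cluster's size against the pool of every
suprathreshold cluster found in the permuted maps thresholded identically;
cluster p = (# null clusters strictly larger) / (total null clusters),
corrected across clusters by Benjamini-Hochberg FDR (default q < 0.05). A
conventional max-statistic cluster null is available as an option.

Group comparisons permute group labels (sign flipping is not valid for
independent groups); format-independence uses a minimum-statistic
conjunction: the voxel-wise maximum p over two decoding directions,
cluster-evaluated against null conjunction maps paired by permutation index.

When ``2^P`` sign patterns fit within the permutation budget the test
enumerates all of them exactly instead of sampling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import rankdata, wilcoxon
from statsmodels.stats.multitest import multipletests

from .grid import VolumeGrid
from .searchlight import CHANCE_LEVEL, maps_to_matrix

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class PermutationSpec:
    """Parameters of the permutation cluster test."""

    n_permutations: int = 50000
    voxel_p_threshold: float = 0.005
    cluster_alpha: float = 0.05
    cluster_null: str = "pooled"  # or "max_stat"
    connectivity: int = 26
    seed: int = 0
    keep_null: bool = True  # retain the permutation p-map stack (conjunction needs it)
    mode: str = "auto"  # auto: enumerate all sign patterns when 2^P <= n_permutations

    def __post_init__(self):
        if self.mode not in ("auto", "exhaustive", "monte_carlo"):
            raise ValueError("mode must be 'auto', 'exhaustive' or 'monte_carlo'")
        if not (0 < self.voxel_p_threshold < 1 and 0 < self.cluster_alpha < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.n_permutations < 100:
            raise ValueError("need at least 100 permutations")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.cluster_null not in ("pooled", "max_stat"):
            raise ValueError("cluster_null must be 'pooled' or 'max_stat'")


@dataclass
class Cluster:
    cluster_id: int
    columns: np.ndarray  # member voxels as masked-vector columns
    size: int
    p: float
    q: float
    peak_stat: float
    peak_voxel: tuple
    peak_mm: tuple
    label: str = ""


@dataclass
class ClusterReport:
    """Suprathreshold clusters with pooled-null cluster p and FDR q."""

    clusters: list
    n_null_clusters: int
    min_resolvable_p: float
    voxel_p_threshold: float
    cluster_alpha: float

    def significant(self) -> list:
        return [c for c in self.clusters if c.q < self.cluster_alpha]

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "size_voxels": c.size,
                "cluster_p": c.p,
                "fdr_q": c.q,
                "peak_stat": c.peak_stat,
                "peak_x_vox": c.peak_voxel[0],
                "peak_y_vox": c.peak_voxel[1],
                "peak_z_vox": c.peak_voxel[2],
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
                "label": c.label,
            }
            for c in self.clusters
        ]
        cols = [
            "cluster_id",
            "size_voxels",
            "cluster_p",
            "fdr_q",
            "peak_stat",
            "peak_x_vox",
            "peak_y_vox",
            "peak_z_vox",
            "peak_x_mm",
            "peak_y_mm",
            "peak_z_mm",
            "label",
        ]
        return pd.DataFrame(rows, columns=cols)


@dataclass
class PermutationResult:
    """Observed statistic, voxel p map, clusters, and the permutation stack."""

    stat: np.ndarray  # (V,) observed statistic (mean accuracy - chance, or difference)
    p: np.ndarray  # (V,) voxel-wise one-sided p
    clusters: ClusterReport
    mode: str  # "exhaustive" or "monte_carlo"
    n_permutations: int
    spec: PermutationSpec
    p_matrix: np.ndarray = field(default=None, repr=False)  # (B, V), row 0 observed


def benjamini_hochberg(p_values) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def label_clusters(binary_map: np.ndarray, connectivity: int = 26):
    """Connected components of a 3-D binary map.

    Returns ``(labels, sizes)`` where ``sizes[i]`` is the voxel count of
    cluster ``i + 1``.
    """
    labels, n = ndimage.label(np.asarray(binary_map, dtype=bool), _STRUCTURES[connectivity])
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


def _sign_patterns(n_participants: int, spec: PermutationSpec):
    """(B, P) matrix of +-1 flips; row 0 is the identity (no flip)."""
    P = n_participants
    exhaust = 2**P <= spec.n_permutations if spec.mode == "auto" else spec.mode == "exhaustive"
    if exhaust:
        if 2**P > 2**22:
            raise ValueError(f"exhaustive enumeration of 2^{P} sign patterns is too large")
        b = np.arange(2**P, dtype=np.int64)
        bits = (b[:, None] >> np.arange(P)) & 1
        return 1.0 - 2.0 * bits, "exhaustive"
    rng = np.random.default_rng(spec.seed)
    flips = rng.choice([-1.0, 1.0], size=(spec.n_permutations, P))
    flips[0] = 1.0
    return flips, "monte_carlo"


def _p_from_null(null_stats: np.ndarray) -> np.ndarray:
    """Per-voxel one-sided p of every permutation against the pooled null.

    ``p[b, v]`` is the fraction of permutations whose statistic at voxel v is
    >= the statistic of permutation b (ties count). Row 0 (identity) yields
    the observed p map.
    """
    B = null_stats.shape[0]
    ranks = rankdata(null_stats, method="min", axis=0)
    return (B - ranks + 1.0) / B


def _cluster_inference(p_matrix, stat, spec, grid) -> ClusterReport:
    """Cluster formation and pooled (or max-stat) null cluster-size inference."""
    binary = p_matrix < spec.voxel_p_threshold
    obs_vol = np.zeros(grid.shape, dtype=bool)
    obs_vol[grid.mask] = binary[0]
    labels, sizes = label_clusters(obs_vol, spec.connectivity)

    # null cluster sizes from the random permutations (rows >= 1)
    null_sizes = []
    max_sizes = []
    vol = np.zeros(grid.shape, dtype=bool)
    for b in range(1, binary.shape[0]):
        row = binary[b]
        if not row.any():
            max_sizes.append(0)
            continue
        vol[:] = False
        vol[grid.mask] = row
        _, s = label_clusters(vol, spec.connectivity)
        null_sizes.extend(s.tolist())
        max_sizes.append(int(s.max()))
    null_sizes = np.asarray(null_sizes, dtype=float)
    max_sizes = np.asarray(max_sizes, dtype=float)

    clusters = []
    colvol = grid.column_index
    mask_coords = grid.mask_coords
    col_of_label = labels[grid.mask]
    for ci, size in enumerate(sizes, start=1):
        cols = np.flatnonzero(col_of_label == ci)
        if spec.cluster_null == "pooled":
            if len(null_sizes):
                p = float(np.mean(null_sizes > size))
            else:
                p = 0.0  # no null clusters at all: below resolution
        else:
            p = float(np.mean(max_sizes >= size)) if len(max_sizes) else 0.0
        peak_local = cols[np.argmax(stat[cols])]
        peak_voxel = tuple(int(x) for x in mask_coords[peak_local])
        peak_mm = tuple(float(x) for x in grid.voxel_to_mm(mask_coords[peak_local])[0])
        clusters.append(
            Cluster(
                cluster_id=ci,
                columns=cols,
                size=int(size),
                p=p,
                q=np.nan,
                peak_stat=float(stat[cols].max()),
                peak_voxel=peak_voxel,
                peak_mm=peak_mm,
            )
        )
    if clusters:
        qs = benjamini_hochberg([c.p for c in clusters])
        for c, q in zip(clusters, qs):
            c.q = float(q)
    n_null = int(len(null_sizes)) if spec.cluster_null == "pooled" else int(len(max_sizes))
    return ClusterReport(
        clusters=clusters,
        n_null_clusters=n_null,
        min_resolvable_p=1.0 / max(n_null, 1),
        voxel_p_threshold=spec.voxel_p_threshold,
        cluster_alpha=spec.cluster_alpha,
    )


def _as_matrix(maps) -> np.ndarray:
    if isinstance(maps, np.ndarray):
        return np.asarray(maps, dtype=float)
    return maps_to_matrix(maps)


def one_sample_permutation(
    maps, spec: PermutationSpec, grid: VolumeGrid, chance: float = CHANCE_LEVEL
) -> PermutationResult:
    """Sign-permutation test of mean accuracy > chance with cluster inference.

    ``maps`` is a list of :class:`AccuracyMap` or a (P, V) matrix of
    accuracies (chance subtracted internally).
    """
    M = _as_matrix(maps)
    if M.shape[0] < 2:
        raise ValueError("need at least two participant maps")
    D = M - chance
    flips, mode = _sign_patterns(D.shape[0], spec)
    null_means = flips @ D / D.shape[0]
    p_matrix = _p_from_null(null_means)
    stat = D.mean(axis=0)
    report = _cluster_inference(p_matrix, stat, spec, grid)
    return PermutationResult(
        stat=stat,
        p=p_matrix[0],
        clusters=report,
        mode=mode,
        n_permutations=p_matrix.shape[0],
        spec=spec,
        p_matrix=p_matrix if spec.keep_null else None,
    )


def two_sample_permutation(
    maps_a, maps_b, spec: PermutationSpec, grid: VolumeGrid
) -> PermutationResult:
    """One-sided group comparison (mean_A - mean_B) by group-label permutation.

    The null reassigns participants to groups preserving group sizes; sign
    flipping is not a valid null for independent groups, so label permutation
    is used even though both arms otherwise share the cluster machinery.
    """
    A = _as_matrix(maps_a)
    B_mat = _as_matrix(maps_b)
    if A.shape[0] < 2 or B_mat.shape[0] < 2:
        raise ValueError("need at least two maps per group")
    X = np.vstack([A, B_mat])
    na = A.shape[0]
    n = X.shape[0]
    rng = np.random.default_rng(spec.seed)
    B = spec.n_permutations
    null = np.empty((B, X.shape[1]))
    null[0] = A.mean(axis=0) - B_mat.mean(axis=0)
    for b in range(1, B):
        idx = rng.permutation(n)
        null[b] = X[idx[:na]].mean(axis=0) - X[idx[na:]].mean(axis=0)
    p_matrix = _p_from_null(null)
    report = _cluster_inference(p_matrix, null[0], spec, grid)
    return PermutationResult(
        stat=null[0],
        p=p_matrix[0],
        clusters=report,
        mode="monte_carlo",
        n_permutations=B,
        spec=spec,
        p_matrix=p_matrix if spec.keep_null else None,
    )


def conjunction(
    result_1: PermutationResult,
    result_2: PermutationResult,
    spec: PermutationSpec,
    grid: VolumeGrid,
) -> PermutationResult:
    """Minimum-statistic conjunction of two decoding directions.

    The voxel-wise conjunction p is the maximum of the two directions'
    p-values (testing the logical AND of both effects). Cluster-size
    inference rebuilds the null by applying the same max rule to the two
    directions' permutation p-maps paired by permutation index (each
    direction keeps its own independent draws).
    """
    p1, p2 = result_1.p_matrix, result_2.p_matrix
    if p1 is None or p2 is None:
        raise ValueError("conjunction needs results computed with keep_null=True")
    if p1.shape != p2.shape:
        raise ValueError("directions must share grid and permutation count")
    conj = np.maximum(p1, p2)
    # peak statistic: mean of the two direction statistics (reported only)
    stat = 0.5 * (result_1.stat + result_2.stat)
    report = _cluster_inference(conj, stat, spec, grid)
    return PermutationResult(
        stat=stat,
        p=conj[0],
        clusters=report,
        mode=result_1.mode,
        n_permutations=conj.shape[0],
        spec=spec,
        p_matrix=conj if spec.keep_null else None,
    )


def residualize_accuracy(maps, covariates: pd.DataFrame):
    """Regress covariates of no interest out of accuracy maps.

    Per voxel, ordinary least squares of accuracy on an intercept plus the
    covariate columns (six motion summaries and IQ in the emulated design)
    across participants; the fitted covariate contribution is subtracted
    while the intercept is kept, so adjusted values stay on the accuracy
    scale around their group mean. Collinear covariate columns are dropped
    with a warning.

    ``maps`` may be a (P, V) matrix (rows must follow ``covariates`` row
    order) or a list of :class:`AccuracyMap` (matched to ``covariates`` by
    participant id).
    """
    as_maps = not isinstance(maps, np.ndarray)
    if as_maps:
        cov = covariates.loc[[m.participant_id for m in maps]]
        Y = maps_to_matrix(maps)
    else:
        cov = covariates
        Y = np.asarray(maps, dtype=float)
    if Y.shape[0] < cov.shape[1] + 2:
        raise ValueError("need more participants than covariates")
    C = np.asarray(cov, dtype=float)
    X = np.column_stack([np.ones(len(C)), C])
    # drop collinear columns (keep the intercept and the first independent set)
    keep = [0]
    for j in range(1, X.shape[1]):
        if np.linalg.matrix_rank(X[:, keep + [j]]) > len(keep):
            keep.append(j)
        else:
            warnings.warn(f"dropping collinear covariate column {cov.columns[j - 1]!r}")
    Xk = X[:, keep]
    beta = np.linalg.lstsq(Xk, Y, rcond=None)[0]
    # subtract the CENTRED covariate fit: the group mean (and with it the
    # chance-level anchor of the accuracy scale) is preserved
    Xc = Xk[:, 1:] - Xk[:, 1:].mean(axis=0)
    adjusted = Y - Xc @ beta[1:]
    if not as_maps:
        return adjusted
    import copy

    out = []
    for m, row in zip(maps, adjusted):
        m2 = copy.copy(m)
        m2.values = row
        out.append(m2)
    return out


def accuracy_histogram_test(mean_map_a, mean_map_b, n_bins: int = 30) -> dict:
    """Paired Wilcoxon signed-rank test across voxels of two mean-accuracy maps.

    Also returns a shared-bin histogram summary of both maps (the figure-level
    comparison of voxelwise accuracy distributions).
    """
    a = np.asarray(mean_map_a, dtype=float)
    b = np.asarray(mean_map_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("maps must cover the same voxel set")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if hi == lo:
        hi = lo + 1e-12
    edges = np.linspace(lo, hi, n_bins + 1)
    hist_a, _ = np.histogram(a, bins=edges)
    hist_b, _ = np.histogram(b, bins=edges)
    out = {
        "bin_edges": edges,
        "counts_a": hist_a,
        "counts_b": hist_b,
        "n_voxels": a.size,
        "median_difference": float(np.median(a - b)),
    }
    if np.allclose(a, b):
        out["p"] = np.nan
        out["note"] = "all-tie input: signed-rank p undefined"
        return out
    res = wilcoxon(a, b)
    out["statistic"] = float(res.statistic)
    out["p"] = float(res.pvalue)
    return out
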