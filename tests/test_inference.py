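"""Permutation inference against exhaustive enumeration and flood-fill oracles."""

import numpy as np
import pandas as pd
import pytest

from helpers import full_grid
from mvpa_adapt.grid import VolumeGrid, ball_mask
from mvpa_adapt.inference import (
    PermutationSpec,
    accuracy_histogram_test,
    benjamini_hochberg,
    conjunction,
    label_clusters,
    one_sample_permutation,
    residualize_accuracy,
    two_sample_permutation,
)

# -- Benjamini-Hochberg --------------------------------------------------------


def bh_oracle(p):
    """Textbook step-up definition, written independently of the package."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


def test_bh_worked_example():
    assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.05]), [0.03, 0.03, 0.05])


def test_bh_matches_oracle_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        p = rng.random(rng.integers(1, 12))
        assert np.allclose(benjamini_hochberg(p), bh_oracle(p))
    # ties and extremes
    for p in ([0.5, 0.5, 0.5], [0.0, 1.0], [1.0], [0.04] * 5 + [1.0]):
        assert np.allclose(benjamini_hochberg(p), bh_oracle(p))


def test_bh_is_order_equivariant_and_validates_input():
    rng = np.random.default_rng(1)
    p = rng.random(9)
    perm = rng.permutation(9)
    assert np.allclose(benjamini_hochberg(p)[perm], benjamini_hochberg(p[perm]))
    assert benjamini_hochberg([]).size == 0
    with pytest.raises(ValueError):
        benjamini_hochberg([0.5, 1.5])


# -- cluster labelling ---------------------------------------------------------


def neighbours(connectivity):
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                manhattan = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and manhattan > 1:
                    continue
                if connectivity == 18 and manhattan > 2:
                    continue
                offs.append((dx, dy, dz))
    return offs


def flood_fill_components(binary, connectivity):
    """Independent BFS labelling; returns a set of frozensets of voxel tuples."""
    offs = neighbours(connectivity)
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    shape = binary.shape
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.add(v)
            for o in offs:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= w[i] < shape[i] for i in range(3)):
                    if binary[w] and not seen[w]:
                        seen[w] = True
                        stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def components_from_labels(labels):
    out = set()
    for lab in range(1, labels.max() + 1):
        out.add(frozenset(zip(*np.nonzero(labels == lab))))
    return out


@pytest.mark.parametrize("connectivity", [6, 18, 26])
def test_label_clusters_matches_flood_fill(connectivity):
    rng = np.random.default_rng(connectivity)
    for density in (0.2, 0.5):
        for _ in range(15):
            binary = rng.random((5, 5, 5)) < density
            labels, sizes = label_clusters(binary, connectivity)
            assert components_from_labels(labels) == flood_fill_components(binary, connectivity)
            assert sorted(sizes) == sorted(len(c) for c in components_from_labels(labels))


def test_label_clusters_connectivity_semantics():
    vol = np.zeros((3, 3, 3), bool)
    vol[0, 0, 0] = vol[1, 1, 1] = True  # corner-sharing pair
    for conn, n in ((6, 2), (18, 2), (26, 1)):
        _, sizes = label_clusters(vol, conn)
        assert len(sizes) == n
    vol2 = np.zeros((3, 3, 3), bool)
    vol2[0, 0, 0] = vol2[0, 0, 1] = True  # face-sharing pair
    _, sizes = label_clusters(vol2, 6)
    assert list(sizes) == [2]
    _, sizes = label_clusters(np.zeros((3, 3, 3), bool), 26)
    assert len(sizes) == 0


# -- one-sample sign permutation -----------------------------------------------


def brute_force_sign_p(D):
    """Voxel p by explicit enumeration of all sign patterns (independent code)."""
    P, V = D.shape
    obs = D.mean(axis=0)
    count = np.zeros(V)
    for b in range(2**P):
        signs = np.array([1.0 if (b >> k) & 1 == 0 else -1.0 for k in range(P)])
        count += (signs @ D) / P >= obs - 1e-12
    return count / 2**P


def test_exhaustive_mode_matches_brute_force_enumeration():
    rng = np.random.default_rng(2)
    grid = full_grid((3, 3, 2))  # 18 voxels
    M = 0.5 + 0.06 * rng.standard_normal((7, grid.n_voxels))
    M[:, :4] += 0.12  # a few genuinely shifted voxels span the p range
    spec = PermutationSpec(n_permutations=1000, seed=0, keep_null=False)
    res = one_sample_permutation(M, spec, grid)
    assert res.mode == "exhaustive" and res.n_permutations == 128
    assert np.allclose(res.p, brute_force_sign_p(M - 0.5))
    assert np.all(res.p >= 1 / 128)


def test_monte_carlo_mode_and_identity_row():
    rng = np.random.default_rng(3)
    grid = full_grid((3, 3, 2))
    M = 0.5 + 0.05 * rng.standard_normal((7, grid.n_voxels))
    spec = PermutationSpec(n_permutations=2000, seed=1, keep_null=False, mode="monte_carlo")
    res = one_sample_permutation(M, spec, grid)
    assert res.mode == "monte_carlo" and res.n_permutations == 2000
    assert np.all(res.p >= 1 / 2000)  # identity row counted
    ex = one_sample_permutation(M, PermutationSpec(n_permutations=2000, seed=1,
                                                   keep_null=False), grid)
    se = np.sqrt(ex.p * (1 - ex.p) / 2000)
    assert np.all(np.abs(res.p - ex.p) <= 3 * se + 2 / 2000)


def test_flat_maps_give_p_one_everywhere():
    grid = full_grid((2, 2, 2))
    M = np.full((6, grid.n_voxels), 0.5)
    res = one_sample_permutation(M, PermutationSpec(n_permutations=500, keep_null=False), grid)
    assert np.all(res.p == 1.0)
    assert len(res.clusters.clusters) == 0


def test_one_sample_requires_two_maps_and_valid_spec():
    grid = full_grid((2, 2, 2))
    with pytest.raises(ValueError):
        one_sample_permutation(np.full((1, grid.n_voxels), 0.6),
                               PermutationSpec(n_permutations=100), grid)
    for bad in (
        dict(voxel_p_threshold=0.0),
        dict(cluster_alpha=1.0),
        dict(n_permutations=10),
        dict(connectivity=4),
        dict(cluster_null="magic"),
        dict(mode="banana"),
    ):
        with pytest.raises(ValueError):
            PermutationSpec(**bad)


def planted_maps(rng, n_maps, grid, region_cols, shift=0.15, noise=0.03):
    M = 0.5 + noise * rng.standard_normal((n_maps, grid.n_voxels))
    M[:, region_cols] += shift
    return M


def region_grid():
    mask = ball_mask((9, 9, 9), 3.5)
    grid = VolumeGrid((9, 9, 9), 2.0, mask)
    center_cols = np.flatnonzero(
        (np.linalg.norm(grid.mask_coords - 4.0, axis=1) <= 1.5)
    )
    return grid, center_cols


def dice(cols_a, cols_b, n):
    a = np.zeros(n, bool)
    b = np.zeros(n, bool)
    a[cols_a] = True
    b[cols_b] = True
    return 2 * (a & b).sum() / (a.sum() + b.sum())


def test_one_sample_recovers_planted_cluster():
    grid, region = region_grid()
    rng = np.random.default_rng(5)
    M = planted_maps(rng, 12, grid, region)
    spec = PermutationSpec(n_permutations=1000, voxel_p_threshold=0.005, seed=2, keep_null=False)
    res = one_sample_permutation(M, spec, grid)
    sig = res.clusters.significant()
    assert len(sig) == 1
    got = np.concatenate([c.columns for c in sig])
    assert dice(got, region, grid.n_voxels) >= 0.8
    peak = sig[0]
    assert peak.peak_stat == pytest.approx(res.stat.max())


def test_max_stat_null_is_at_least_as_conservative_as_pooled():
    grid, region = region_grid()
    rng = np.random.default_rng(6)
    M = planted_maps(rng, 10, grid, region, shift=0.08, noise=0.05)
    pooled = one_sample_permutation(
        M, PermutationSpec(n_permutations=500, seed=3, cluster_null="pooled",
                           keep_null=False), grid)
    maxstat = one_sample_permutation(
        M, PermutationSpec(n_permutations=500, seed=3, cluster_null="max_stat",
                           keep_null=False), grid)
    assert [c.size for c in pooled.clusters.clusters] == [c.size for c in maxstat.clusters.clusters]
    for cp, cm in zip(pooled.clusters.clusters, maxstat.clusters.clusters):
        assert cm.p >= cp.p - 1e-12


def test_lower_voxel_threshold_shrinks_clusters():
    grid, region = region_grid()
    rng = np.random.default_rng(7)
    M = planted_maps(rng, 10, grid, region, shift=0.1, noise=0.06)
    loose = one_sample_permutation(
        M, PermutationSpec(n_permutations=600, voxel_p_threshold=0.1, seed=4,
                           keep_null=False), grid)
    strict = one_sample_permutation(
        M, PermutationSpec(n_permutations=600, voxel_p_threshold=0.02, seed=4,
                           keep_null=False), grid)
    loose_union = set(np.concatenate([c.columns for c in loose.clusters.clusters]).tolist()
                      ) if loose.clusters.clusters else set()
    for c in strict.clusters.clusters:
        cols = set(c.columns.tolist())
        assert cols <= loose_union
        # every strict cluster lies within exactly one loose cluster
        assert sum(bool(cols & set(lc.columns.tolist())) for lc in loose.clusters.clusters) == 1


# -- two-sample ----------------------------------------------------------------


def test_two_sample_statistic_is_antisymmetric():
    grid = full_grid((3, 3, 3))
    rng = np.random.default_rng(8)
    A = 0.5 + 0.05 * rng.standard_normal((5, grid.n_voxels))
    B = 0.5 + 0.05 * rng.standard_normal((6, grid.n_voxels))
    spec = PermutationSpec(n_permutations=300, seed=5, keep_null=False)
    ab = two_sample_permutation(A, B, spec, grid)
    ba = two_sample_permutation(B, A, spec, grid)
    assert np.allclose(ab.stat, -ba.stat)
    assert np.allclose(ab.stat, A.mean(axis=0) - B.mean(axis=0))


def test_two_sample_detects_planted_group_difference():
    grid, region = region_grid()
    rng = np.random.default_rng(9)
    A = planted_maps(rng, 10, grid, region, shift=0.15, noise=0.03)
    B = 0.5 + 0.03 * rng.standard_normal((10, grid.n_voxels))
    spec = PermutationSpec(n_permutations=1000, voxel_p_threshold=0.01, seed=6, keep_null=False)
    res = two_sample_permutation(A, B, spec, grid)
    sig = res.clusters.significant()
    assert sig
    got = np.concatenate([c.columns for c in sig])
    assert dice(got, region, grid.n_voxels) >= 0.6
    null = two_sample_permutation(B, A, spec, grid)
    assert not null.clusters.significant()


# -- conjunction ---------------------------------------------------------------


def test_conjunction_p_is_elementwise_max_and_idempotent():
    grid, region = region_grid()
    rng = np.random.default_rng(10)
    M = planted_maps(rng, 10, grid, region)
    spec = PermutationSpec(n_permutations=400, seed=7, keep_null=True)
    res = one_sample_permutation(M, spec, grid)
    conj = conjunction(res, res, spec, grid)
    assert np.array_equal(conj.p, res.p)
    assert [c.size for c in conj.clusters.clusters] == [c.size for c in res.clusters.clusters]
    # dominance against a second, independent direction
    M2 = planted_maps(np.random.default_rng(11), 10, grid, region, shift=0.05)
    res2 = one_sample_permutation(
        M2, PermutationSpec(n_permutations=400, seed=8, keep_null=True), grid)
    both = conjunction(res, res2, spec, grid)
    assert np.all(both.p >= res.p - 1e-12)
    assert np.all(both.p >= res2.p - 1e-12)


def test_conjunction_rejects_mismatched_or_discarded_nulls():
    grid = full_grid((2, 2, 2))
    rng = np.random.default_rng(12)
    M = 0.5 + 0.05 * rng.standard_normal((6, grid.n_voxels))
    keep = PermutationSpec(n_permutations=200, seed=9, keep_null=True)
    drop = PermutationSpec(n_permutations=200, seed=9, keep_null=False)
    with pytest.raises(ValueError):
        conjunction(one_sample_permutation(M, drop, grid),
                    one_sample_permutation(M, keep, grid), keep, grid)
    other = one_sample_permutation(M[:5], keep, grid)
    with pytest.raises(ValueError):
        conjunction(one_sample_permutation(M, keep, grid), other, keep, grid)


def test_conjunction_is_null_when_one_direction_is_null():
    grid, region = region_grid()
    rng = np.random.default_rng(13)
    strong = planted_maps(rng, 12, grid, region, shift=0.2, noise=0.03)
    flat = 0.5 + 0.03 * rng.standard_normal((12, grid.n_voxels))
    spec = PermutationSpec(n_permutations=500, seed=10, keep_null=True)
    r1 = one_sample_permutation(strong, spec, grid)
    r2 = one_sample_permutation(
        flat, PermutationSpec(n_permutations=500, seed=11, keep_null=True), grid)
    assert r1.clusters.significant()
    conj = conjunction(r1, r2, spec, grid)
    assert not conj.clusters.significant()


# -- residualization -----------------------------------------------------------


def covariate_frame(n, rng):
    cols = ["trans_x", "trans_y", "trans_z", "rot_roll", "rot_pitch", "rot_yaw", "iq"]
    return pd.DataFrame(rng.standard_normal((n, len(cols))), columns=cols,
                        index=[f"sub-{i:02d}" for i in range(n)])


def test_residualize_removes_known_iq_dependence_exactly():
    rng = np.random.default_rng(14)
    cov = covariate_frame(12, rng)
    base = 0.5 + 0.02 * rng.standard_normal(30)
    Y = np.tile(base, (12, 1)) + 0.03 * cov["iq"].to_numpy()[:, None]
    adj = residualize_accuracy(Y, cov)
    # per voxel, zero correlation with every covariate afterwards
    centred = adj - adj.mean(axis=0)
    for c in cov.columns:
        x = cov[c].to_numpy()
        x = x - x.mean()
        assert np.max(np.abs(centred.T @ x)) < 1e-8
    # pure-IQ maps collapse to a constant per voxel
    assert np.max(adj.std(axis=0)) < 1e-10


def test_residualize_is_idempotent_and_keeps_scale():
    rng = np.random.default_rng(15)
    cov = covariate_frame(15, rng)
    Y = 0.5 + 0.05 * rng.standard_normal((15, 20))
    adj = residualize_accuracy(Y, cov)
    assert np.allclose(residualize_accuracy(adj, cov), adj, atol=1e-10)
    assert np.allclose(adj.mean(axis=0), Y.mean(axis=0), atol=1e-10)  # intercept kept


def test_residualize_drops_collinear_columns_with_warning():
    rng = np.random.default_rng(16)
    cov = covariate_frame(12, rng)
    cov["iq"] = 2.0 * cov["trans_x"] - cov["trans_y"]
    Y = 0.5 + 0.05 * rng.standard_normal((12, 10))
    with pytest.warns(UserWarning, match="collinear"):
        adj = residualize_accuracy(Y, cov)
    solo = residualize_accuracy(Y, cov.drop(columns="iq"))
    assert np.allclose(adj, solo)


def test_residualize_needs_enough_participants():
    rng = np.random.default_rng(17)
    cov = covariate_frame(8, rng)  # 7 covariates need >= 9 participants
    with pytest.raises(ValueError, match="participants"):
        residualize_accuracy(0.5 + rng.standard_normal((8, 5)), cov)


# -- histogram comparison ------------------------------------------------------


def test_accuracy_histogram_test_outputs():
    rng = np.random.default_rng(18)
    a = 0.5 + 0.05 * rng.standard_normal(400)
    b = a + 0.04
    out = accuracy_histogram_test(b, a)
    assert out["p"] < 1e-6
    assert out["median_difference"] == pytest.approx(0.04)
    assert out["counts_a"].sum() == out["counts_b"].sum() == 400
    assert len(out["bin_edges"]) == 31

    tie = accuracy_histogram_test(a, a)
    assert np.isnan(tie["p"]) and "all-tie" in tie["note"]

    with pytest.raises(ValueError):
        accuracy_histogram_test(a, a[:10])
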