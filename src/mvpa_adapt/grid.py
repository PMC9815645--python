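"""Voxel lattice, gray-matter mask and searchlight sphere geometry.

All statistic maps in this package live on a :class:`VolumeGrid`: a common
3-D voxel lattice with an affine mapping voxel indices to scanner (mm)
coordinates and a boolean gray-matter mask. Masked maps are stored as flat
vectors of length ``grid.n_voxels`` ordered like ``grid.mask_coords``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sphere_offsets(radius: float) -> np.ndarray:
    """Integer lattice offsets within Euclidean distance ``radius`` of the origin.

    Distance is measured in voxel-index units, so a radius of 5 on a 2 mm
    isotropic grid corresponds to a 10 mm sphere.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    offs = np.stack([dx[keep], dy[keep], dz[keep]], axis=1)
    # lexicographic order makes membership lists reproducible
    order = np.lexsort((offs[:, 2], offs[:, 1], offs[:, 0]))
    return offs[order]


@dataclass
class VolumeGrid:
    """Common voxel lattice all maps live on.

    Parameters
    ----------
    shape : tuple of 3 ints
        Voxels per axis.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in mm.
    mask : ndarray of bool, shape ``shape``
        Gray-matter mask; analyses are restricted to True voxels.
    affine : (4, 4) ndarray, optional
        Voxel-index -> mm mapping. Defaults to a diagonal scaling that puts
        the grid center at the origin.
    """

    shape: tuple
    voxel_size_mm: tuple
    mask: np.ndarray
    affine: np.ndarray = None
    _coords: np.ndarray = field(default=None, repr=False, compare=False)
    _colindex: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if np.isscalar(self.voxel_size_mm):
            self.voxel_size_mm = (float(self.voxel_size_mm),) * 3
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.shape:
            raise ValueError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValueError("mask must contain at least one voxel")
        if self.affine is None:
            vs = np.asarray(self.voxel_size_mm)
            center = (np.asarray(self.shape) - 1) / 2.0
            aff = np.eye(4)
            aff[:3, :3] = np.diag(vs)
            aff[:3, 3] = -vs * center
            self.affine = aff
        self.affine = np.asarray(self.affine, dtype=float)

    # -- derived geometry ---------------------------------------------------

    @property
    def n_voxels(self) -> int:
        """Number of mask voxels (length of masked map vectors)."""
        return int(self.mask.sum())

    @property
    def mask_coords(self) -> np.ndarray:
        """(V, 3) integer coordinates of mask voxels, C order."""
        if self._coords is None:
            self._coords = np.argwhere(self.mask)
        return self._coords

    @property
    def column_index(self) -> np.ndarray:
        """3-D int volume mapping each mask voxel to its vector column, -1 outside."""
        if self._colindex is None:
            idx = np.full(self.shape, -1, dtype=np.int64)
            idx[self.mask] = np.arange(self.n_voxels)
            self._colindex = idx
        return self._colindex

    def embed(self, vec: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a masked vector back into a full 3-D volume."""
        vec = np.asarray(vec)
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.mask] = vec
        return vol

    def extract(self, volume: np.ndarray) -> np.ndarray:
        """Flatten a 3-D volume to the masked vector representation."""
        return np.asarray(volume)[self.mask]

    def voxel_to_mm(self, voxels: np.ndarray) -> np.ndarray:
        voxels = np.atleast_2d(voxels)
        hom = np.c_[voxels, np.ones(len(voxels))]
        return (self.affine @ hom.T).T[:, :3]

    # -- searchlight --------------------------------------------------------

    def sphere_members(self, center, radius: float) -> np.ndarray:
        """Column indices of mask voxels within ``radius`` of ``center``.

        ``center`` must itself be a mask voxel; the returned set is the
        sphere intersected with the mask and always contains the center.
        """
        center = np.asarray(center, dtype=int)
        if not self.mask[tuple(center)]:
            raise ValueError("sphere center must lie inside the mask")
        pts = center + sphere_offsets(radius)
        ok = np.all((pts >= 0) & (pts < np.asarray(self.shape)), axis=1)
        pts = pts[ok]
        cols = self.column_index[pts[:, 0], pts[:, 1], pts[:, 2]]
        return cols[cols >= 0]

    def sphere_columns(self, radius: float) -> list:
        """Sphere membership (column-index arrays) for every mask voxel.

        Vectorized over centers; entry ``i`` corresponds to
        ``mask_coords[i]`` as center.
        """
        offs = sphere_offsets(radius)
        coords = self.mask_coords
        shape = np.asarray(self.shape)
        out = []
        colvol = self.column_index
        for c in coords:
            pts = c + offs
            ok = np.all((pts >= 0) & (pts < shape), axis=1)
            p = pts[ok]
            cols = colvol[p[:, 0], p[:, 1], p[:, 2]]
            out.append(cols[cols >= 0])
        return out


def ball_mask(shape, radius: float, center=None) -> np.ndarray:
    """Boolean ball of given voxel radius, a simple synthetic gray-matter mask."""
    shape = tuple(int(s) for s in shape)
    if center is None:
        center = (np.asarray(shape) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def ellipsoid_mask(shape, margin: int = 1) -> np.ndarray:
    """Inscribed ellipsoid mask leaving ``margin`` empty voxels at each face."""
    shape = np.asarray(shape, dtype=int)
    center = (shape - 1) / 2.0
    semi = np.maximum((shape - 1) / 2.0 - margin, 0.5)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    d2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return d2 <= 1.0


def ball_region(center, radius: float, shape) -> np.ndarray:
    """(K, 3) voxel coordinates of a ball-shaped effect region inside ``shape``."""
    center = np.asarray(center, dtype=int)
    pts = center + sphere_offsets(radius)
    ok = np.all((pts >= 0) & (pts < np.asarray(shape)), axis=1)
    return pts[ok]
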