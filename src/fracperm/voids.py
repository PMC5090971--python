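"""Transient-void detection in periodic molecular configurations.

Non-hydrogen atoms are treated as spheres of radius R_min/2 (from a
user-supplied radius table) plus a probe radius; the periodic cell is
tiled with a ~0.5 Å voxel grid and each voxel whose centre falls inside
any inflated atomic sphere (minimum-image convention) is marked occupied.
Contiguous empty voxels under 26-neighbour connectivity with periodic
wrapping form voids; each void is characterized by its volume and its
z-extent σ_z (standard deviation of voxel z positions, unwrapped by
minimum image relative to the void's first voxel).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .profiles import Profile
from .synth import AtomicConfiguration

__all__ = ["OccupancyGrid", "VoidLabeling", "mark_occupancy",
           "flood_fill_voids", "void_statistics", "empty_fraction_profile",
           "permeant_adjacent_void"]

_HYDROGEN = {"H", "h", "1"}


def _is_hydrogen(t: str) -> bool:
    return str(t).strip()[:1] in _HYDROGEN


@dataclass
class OccupancyGrid:
    occupied: np.ndarray          # bool (nx, ny, nz)
    spacing: np.ndarray           # per-axis voxel size, Å
    cell: np.ndarray              # orthorhombic cell lengths, Å

    @property
    def shape(self):
        return self.occupied.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def centers(self, axis: int) -> np.ndarray:
        n = self.occupied.shape[axis]
        return (np.arange(n) + 0.5) * self.spacing[axis]


@dataclass
class VoidLabeling:
    grid: OccupancyGrid
    labels: np.ndarray            # 0 = occupied, 1..n_voids = void id
    n_voids: int
    stats: list = field(default_factory=list)


def _grid_shape(cell, spacing):
    # per-axis spacing = cell / round(cell / target) so the grid tiles the
    # periodic cell exactly
    n = np.maximum(np.rint(np.asarray(cell) / spacing).astype(int), 1)
    return n, np.asarray(cell) / n


def mark_occupancy(config: AtomicConfiguration, probe_radius: float = 1.5,
                   spacing: float = 0.5, include_hydrogens: bool = False,
                   exclude_indices=None) -> OccupancyGrid:
    """Mark voxels whose centre lies within (type radius + probe) of an atom.

    Hydrogen atoms are skipped by default; ``exclude_indices`` removes
    specific atoms (e.g. the permeant) from the occupancy computation.
    """
    cell = np.asarray(config.cell, float)
    shape, sp = _grid_shape(cell, spacing)
    occ = np.zeros(shape, dtype=bool)
    excl = set() if exclude_indices is None else set(int(i)
                                                    for i in exclude_indices)
    for i in range(config.n_atoms):
        if i in excl:
            continue
        if not include_hydrogens and _is_hydrogen(config.types[i]):
            continue
        R = config.radius_of(i) + probe_radius
        pos = np.mod(config.coords[i], cell)
        # wrapped voxel-index window covering the inflated sphere
        idx, d2 = [], []
        for d in range(3):
            lo = int(np.floor((pos[d] - R) / sp[d] - 0.5))
            hi = int(np.ceil((pos[d] + R) / sp[d] - 0.5))
            if hi - lo + 1 >= shape[d]:  # sphere wraps the whole axis
                js = np.arange(shape[d])
            else:
                js = np.arange(lo, hi + 1)
            dd = np.abs((js + 0.5) * sp[d] - pos[d])
            dd = np.minimum(dd, cell[d] - dd)  # minimum image
            idx.append(np.mod(js, shape[d]))
            d2.append(dd ** 2)
        mask = (d2[0][:, None, None] + d2[1][None, :, None]
                + d2[2][None, None, :]) <= R * R
        sub = occ[np.ix_(idx[0], idx[1], idx[2])]
        occ[np.ix_(idx[0], idx[1], idx[2])] = sub | mask
    return OccupancyGrid(occ, sp, cell)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def flood_fill_voids(grid: OccupancyGrid) -> VoidLabeling:
    """Label contiguous empty regions (26-connectivity, periodic wrapping).

    scipy's connected-component labelling handles the bulk; labels touching
    opposite faces are then merged by union–find to honour the periodic
    boundary.  Final labels are ordered by descending voxel count, ties
    broken by the smallest linear voxel index, so the labelling is
    deterministic.
    """
    empty = ~grid.occupied
    lab, n = ndimage.label(empty, structure=_STRUCT26)
    if n == 0:
        return VoidLabeling(grid, lab, 0)
    parent = np.arange(n + 1)

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    # merge across each periodic face: voxels in the first and last slab
    # are neighbours if their cross indices differ by <= 1 (mod size)
    for axis in range(3):
        first = np.take(lab, 0, axis=axis)
        last = np.take(lab, -1, axis=axis)
        for da in (-1, 0, 1):
            for db in (-1, 0, 1):
                shifted = np.roll(np.roll(last, da, axis=0), db, axis=1)
                m = (first > 0) & (shifted > 0)
                for a, b in zip(first[m].ravel(), shifted[m].ravel()):
                    union(int(a), int(b))
    roots = np.array([find(i) for i in range(n + 1)])
    lab = roots[lab]
    # deterministic relabeling: by descending size, ties by smallest index
    ids, first_idx = np.unique(lab.ravel(), return_index=True)
    sizes = np.bincount(lab.ravel())
    order = [i for i in ids if i != 0]
    order.sort(key=lambda i: (-sizes[i], first_idx[list(ids).index(i)]))
    remap = np.zeros(lab.max() + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    out = VoidLabeling(grid, remap[lab], len(order))
    out.stats = void_statistics(out)
    return out


def _sigma_z(zs: np.ndarray, Lz: float) -> float:
    """Population std of z positions, unwrapped by minimum image.

    ζ_i = I(z_i - z_1) + z_1 with I the minimum-image displacement, so a
    void wrapped across the z face gives the same spread as its unwrapped
    translate.
    """
    z1 = zs[0]
    d = zs - z1
    d -= Lz * np.rint(d / Lz)
    zeta = z1 + d
    return float(np.std(zeta))


def void_statistics(labeling: VoidLabeling) -> list:
    """Per-void volume (Å³) and z-extent σ_z (Å)."""
    g = labeling.grid
    vv = g.voxel_volume
    zc = g.centers(2)
    Lz = g.cell[2]
    out = []
    for vid in range(1, labeling.n_voids + 1):
        idx = np.argwhere(labeling.labels == vid)
        zs = zc[idx[:, 2]]
        out.append({"id": vid, "voxels": int(idx.shape[0]),
                    "volume": idx.shape[0] * vv,
                    "sigma_z": _sigma_z(zs, Lz)})
    return out


def empty_fraction_profile(labeling: VoidLabeling,
                           z_bin_width: float | None = None) -> Profile:
    """Fraction of empty voxels per z slab (z measured from the cell base)."""
    g = labeling.grid
    empty = labeling.labels > 0
    frac = empty.mean(axis=(0, 1))
    zc = g.centers(2)
    if z_bin_width is not None and z_bin_width > g.spacing[2]:
        per = max(int(round(z_bin_width / g.spacing[2])), 1)
        nb = zc.size // per
        frac = frac[:nb * per].reshape(nb, per).mean(axis=1)
        zc = zc[:nb * per].reshape(nb, per).mean(axis=1)
    return Profile.from_z(zc, frac, "dimensionless")


def permeant_adjacent_void(config: AtomicConfiguration,
                           permeant_indices, probe_radius: float = 1.5,
                           spacing: float = 0.5) -> float:
    """Total volume (Å³) of voids adjacent to the permeant.

    The occupancy is recomputed with the permeant atoms excluded; every
    void component with at least one voxel within (probe + max permeant
    radius) of a permeant atom counts as adjacent.  Returns 0 when no
    empty space touches the permeant.
    """
    permeant_indices = list(permeant_indices)
    if not permeant_indices:
        raise ValueError("empty permeant selection")
    grid = mark_occupancy(config, probe_radius, spacing,
                          exclude_indices=permeant_indices)
    labeling = flood_fill_voids(grid)
    if labeling.n_voids == 0:
        return 0.0
    rmax = max(config.radius_of(i) for i in permeant_indices)
    R = probe_radius + rmax
    cell = grid.cell
    axes = [grid.centers(d) for d in range(3)]
    adjacent = np.zeros(labeling.n_voids + 1, dtype=bool)
    for i in permeant_indices:
        pos = np.mod(config.coords[i], cell)
        d2 = []
        for d in range(3):
            dd = np.abs(axes[d] - pos[d])
            dd = np.minimum(dd, cell[d] - dd)
            d2.append(dd ** 2)
        near = (d2[0][:, None, None] + d2[1][None, :, None]
                + d2[2][None, None, :]) <= R * R
        ids = np.unique(labeling.labels[near])
        adjacent[ids[ids > 0]] = True
    vv = grid.voxel_volume
    total = sum(s["volume"] for s in labeling.stats
                if adjacent[s["id"]])
    return float(total)
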