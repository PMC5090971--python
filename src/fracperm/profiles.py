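"""One-dimensional profiles along the membrane normal and PMF assembly.

The free-energy profile w(z) (PMF) is assembled from stratified-window
mean-force data: each window contributes per-bin sample counts n_s(z) and
mean free-energy gradients g_s(z).  Windows are combined by a count-weighted
average, optionally antisymmetrized (for a symmetric bilayer the PMF must
satisfy w(z) = w(-z)), integrated by the trapezoidal rule, and anchored so
that w has zero mean over a bulk-water interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Profile",
    "GradientWindow",
    "combine_windows",
    "antisymmetrize_gradient",
    "integrate_gradient",
    "halves_uncertainty",
]


@dataclass
class Profile:
    """Values sampled on a uniform z grid.

    Parameters
    ----------
    z0 : float
        Grid origin in Å.
    h : float
        Grid spacing in Å (must be > 0).
    values : ndarray
        Finite values at the grid nodes (length >= 2).
    units : str
        Units tag, e.g. ``kcal/mol``, ``kcal/mol/Å``, ``Å²/ns``,
        ``Å²/ns^α``, ``dimensionless``, ``counts``.
    """

    z0: float
    h: float
    values: np.ndarray
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.h <= 0:
            raise ValueError("grid spacing h must be positive")
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("profile needs at least two nodes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def z(self) -> np.ndarray:
        return self.z0 + self.h * np.arange(self.n)

    @property
    def z1(self) -> float:
        return self.z0 + self.h * (self.n - 1)

    def at(self, z, kind: str = "linear"):
        """Interpolate the profile at arbitrary z (linear or cubic)."""
        z = np.asarray(z, dtype=float)
        if kind == "linear":
            return np.interp(z, self.z, self.values)
        from scipy.interpolate import CubicSpline

        return CubicSpline(self.z, self.values)(z)

    def index_of(self, z: float) -> int:
        """Index of the grid node nearest to z."""
        i = int(round((z - self.z0) / self.h))
        return min(max(i, 0), self.n - 1)

    @classmethod
    def from_z(cls, z: np.ndarray, values: np.ndarray, units: str = "", **meta):
        z = np.asarray(z, dtype=float)
        dz = np.diff(z)
        if not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-9):
            raise ValueError("grid must be uniformly spaced")
        return cls(float(z[0]), float(dz[0]), np.asarray(values, float), units,
                   dict(meta))

    def copy(self, values=None) -> "Profile":
        return Profile(self.z0, self.h,
                       self.values.copy() if values is None else values,
                       self.units, dict(self.meta))


@dataclass
class GradientWindow:
    """Per-window stratified mean-force data.

    ``n`` holds per-bin force-sample counts and ``g`` the per-bin mean
    free-energy gradient (kcal/mol/Å); bin centres are uniformly spaced with
    width ``bin_width`` strictly inside [z_lo, z_hi].
    """

    window_id: str
    z_lo: float
    z_hi: float
    bin_width: float
    n: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        self.n = np.asarray(self.n, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.n.shape != self.g.shape:
            raise ValueError("count and gradient arrays must match")
        if np.any(self.n < 0):
            raise ValueError("counts must be non-negative")
        if np.any(~np.isfinite(self.g) & (self.n > 0)):
            raise ValueError("gradient must be finite wherever counts > 0")
        nb = int(round((self.z_hi - self.z_lo) / self.bin_width))
        if nb != self.n.size:
            raise ValueError(
                f"window {self.window_id}: expected {nb} bins, got {self.n.size}")

    @property
    def centers(self) -> np.ndarray:
        return self.z_lo + self.bin_width * (np.arange(self.n.size) + 0.5)


def _target_centers(z_lo, z_hi, bin_width):
    nb = int(round((z_hi - z_lo) / bin_width))
    return z_lo + bin_width * (np.arange(nb) + 0.5)


def combine_windows(windows, z_lo=-45.0, z_hi=45.0, bin_width=None):
    """Combine stratified windows by the count-weighted gradient average.

    g(z) = Σ_s n_s(z) g_s(z) / Σ_s n_s(z), with n_s(z) = 0 outside window s.

    Interior bins with zero total count are bridged by linear interpolation
    from flanking non-empty bins and flagged in the output metadata; a
    contiguous empty interior gap wider than one bin raises.

    Returns
    -------
    (gradient, counts) : tuple of Profile
        Both on bin centres of the target grid (units kcal/mol/Å, counts).
    """
    if not windows:
        raise ValueError("empty window list")
    if bin_width is None:
        bin_width = windows[0].bin_width
    centers = _target_centers(z_lo, z_hi, bin_width)
    num = np.zeros_like(centers)
    den = np.zeros_like(centers)
    for w in windows:
        if abs(w.bin_width / bin_width - 1) > 1e-9:
            raise ValueError("window bin grid not commensurate with target")
        # locate each window bin on the target grid
        i0 = (w.centers - centers[0]) / bin_width
        idx = np.rint(i0).astype(int)
        if np.any(np.abs(i0 - idx) > 1e-3):  # tolerate text-format rounding
            raise ValueError("window bin centres not aligned with target grid")
        ok = (idx >= 0) & (idx < centers.size)
        num[idx[ok]] += w.n[ok] * np.where(w.n[ok] > 0, w.g[ok], 0.0)
        den[idx[ok]] += w.n[ok]

    empty = den == 0
    g = np.where(empty, np.nan, num / np.where(empty, 1.0, den))
    filled = []
    if np.any(empty):
        # interior gaps: bridge single-bin holes, error on wider ones
        interior = empty.copy()
        runs = _runs(interior)
        for a, b in runs:
            if a == 0 or b == centers.size:  # edge gap: leave flagged, zero g
                g[a:b] = 0.0
                continue
            if b - a > 1:
                raise ValueError(
                    f"zero-count interior gap of {b - a} bins near z = "
                    f"{centers[a]:.2f} Å (unbridgeable)")
            g[a:b] = 0.5 * (g[a - 1] + g[b])
            filled.extend(range(a, b))
    grad = Profile.from_z(centers, g, "kcal/mol/Å", filled_bins=filled,
                          empty_bins=np.flatnonzero(empty).tolist())
    cnt = Profile.from_z(centers, den, "counts")
    return grad, cnt


def _runs(mask):
    """Contiguous True runs of a boolean mask as (start, stop) pairs."""
    out = []
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def _mirror_values(profile: Profile):
    """Values of a profile at the mirrored nodes -z.

    Exact node lookup when the grid is symmetric about z = 0; linear
    interpolation otherwise (the mirror then holds only to interpolation
    error).
    """
    z = profile.z
    zm = -z
    # symmetric grid: -z hits nodes exactly
    if abs((z[0] + z[-1])) < 1e-9 * max(1.0, abs(z[-1])):
        return profile.values[::-1].copy()
    return np.interp(zm, z, profile.values)


def antisymmetrize_gradient(gradient: Profile, counts: Profile) -> Profile:
    """Antisymmetrize the mean-force gradient of a symmetric bilayer.

    g_sym(z) = [n(z) g(z) - n(-z) g(-z)] / [n(z) + n(-z)], so that
    g_sym(-z) = -g_sym(z) holds exactly on the grid nodes.
    """
    if gradient.n != counts.n or abs(gradient.z0 - counts.z0) > 1e-9:
        raise ValueError("gradient and counts must share a grid")
    n = counts.values
    g = gradient.values
    nm = _mirror_values(counts)
    gm = _mirror_values(gradient)
    tot = n + nm
    if np.any(tot == 0):
        raise ValueError("n(z) + n(-z) = 0 at some node")
    out = (n * g - nm * gm) / tot
    return gradient.copy(values=out)


def integrate_gradient(gradient: Profile, anchor=(-45.0, -43.0)) -> Profile:
    """Trapezoidal cumulative integral of the gradient, anchored to zero mean.

    The integration constant is chosen so that w(z) has zero mean over the
    anchor interval (bulk water), making w comparable across assemblies and
    valid for the solubility–diffusion integral.
    """
    z = gradient.z
    za, zb = anchor
    if za < z[0] - gradient.h or zb > z[-1] + gradient.h or za >= zb:
        raise ValueError("anchor interval outside profile domain")
    w = np.concatenate([[0.0], np.cumsum(
        0.5 * (gradient.values[1:] + gradient.values[:-1]) * np.diff(z))])
    mask = (z >= za) & (z <= zb)
    if not np.any(mask):
        raise ValueError("anchor interval contains no grid nodes")
    w -= w[mask].mean()
    return Profile.from_z(z, w, "kcal/mol", anchor=list(anchor))


def halves_uncertainty(first_half, second_half, anchor=(-45.0, -43.0)) -> Profile:
    """Statistical uncertainty of w(z) from first/second-half mean forces.

    The per-bin force standard error is taken as |g_first - g_second| / 2 and
    propagated as independent bin variances accumulated outward from the
    anchor interval: σ_w(z)² = Σ_bins (σ_g Δz)² over bins between the anchor
    and z.

    Parameters
    ----------
    first_half, second_half : (gradient, counts) tuples of Profile
        Window-combined gradients from the two halves of the sampling, on
        identical grids.
    """
    g1, _ = first_half
    g2, _ = second_half
    if g1.n != g2.n or abs(g1.z0 - g2.z0) > 1e-9 or abs(g1.h - g2.h) > 1e-12:
        raise ValueError("half grids do not match")
    z = g1.z
    sigma_g = np.abs(g1.values - g2.values) / 2.0
    var_bin = (sigma_g * g1.h) ** 2
    za, zb = anchor
    zc = 0.5 * (za + zb)
    i0 = int(np.argmin(np.abs(z - zc)))
    var = np.empty_like(var_bin)
    var[i0] = 0.0
    # accumulate independent bin variances outward from the anchor
    for i in range(i0 + 1, z.size):
        var[i] = var[i - 1] + var_bin[i]
    for i in range(i0 - 1, -1, -1):
        var[i] = var[i + 1] + var_bin[i]
    return Profile.from_z(z, np.sqrt(var), "kcal/mol", anchor=list(anchor))
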