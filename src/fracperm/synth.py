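"""Synthetic data with known ground truth for every analysis stage.

Generators:

* ``brownian_trajectory`` — overdamped (Itô) Brownian dynamics on a given
  w(z)/D(z) landscape with reflecting walls; realizes the ideal classical
  control against which the inference and diagnostics are validated.
* ``fbm_trajectory`` — fractional Brownian motion with exact-covariance
  increments (circulant embedding), the anti-persistent surrogate
  (H < 1/2 gives negatively correlated increments, MSD ∝ t^2H).
* ``ctrw_trajectory`` / ``ctrw_ensemble`` — continuous-time random walk
  with Pareto-tailed waiting times of index α, whose hydrodynamic limit is
  the time-fractional diffusion equation (ensemble MSD ∝ t^α).
* ``synthetic_windows`` — noisy stratified-window mean-force data from a
  known PMF.
* ``packing_with_cavity`` — dense random sphere packing with a planted
  empty cavity, the fixture for void detection.

All generators are deterministic under a fixed seed and echo their
parameters into the output metadata.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit
from scipy.interpolate import CubicSpline

from .profiles import GradientWindow, Profile
from .trajectory import Trajectory

__all__ = ["brownian_trajectory", "fbm_trajectory", "fgn",
           "ctrw_trajectory", "ctrw_ensemble", "synthetic_windows",
           "packing_with_cavity", "AtomicConfiguration"]


# ---------------------------------------------------------------------------
# Brownian dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bd_loop(z0, drift_tab, sig_tab, z_lo, z_hi, htab, nsteps, sample_every,
             noise, out):
    z = z0
    ntab = drift_tab.size
    j = 0
    for s in range(nsteps):
        u = (z - z_lo) / htab
        i = int(u)
        if i < 0:
            i = 0
        elif i >= ntab - 1:
            i = ntab - 2
        f = u - i
        drift = drift_tab[i] * (1 - f) + drift_tab[i + 1] * f
        sig = sig_tab[i] * (1 - f) + sig_tab[i + 1] * f
        z = z + drift + sig * noise[s]
        # reflecting walls
        while z < z_lo or z > z_hi:
            if z < z_lo:
                z = 2 * z_lo - z
            else:
                z = 2 * z_hi - z
        if (s + 1) % sample_every == 0:
            out[j] = z
            j += 1
    return j


def brownian_trajectory(w: Profile | None, D: Profile, T: float = 308.0,
                        dt: float = 5e-5, steps: int = 200_000,
                        sample_every: int = 20, z_init: float = 0.0,
                        seed: int = 0, domain=None) -> Trajectory:
    """Overdamped Brownian dynamics on a w(z)/D(z) landscape.

    Itô update with the spurious-drift term,

        z ← z + [β D(z) F(z) + D'(z)] dt + sqrt(2 D(z) dt) ξ,

    so the stationary density is exp(-βw) regardless of D(z) — matching the
    Smoluchowski equation the solvers integrate.  Reflecting walls at the
    domain edges.

    Parameters
    ----------
    w : Profile or None
        PMF (kcal/mol); None means a flat landscape.
    D : Profile
        Diffusivity (Å²/ns).
    dt : float
        Integration step (ns); must satisfy D dt ≪ domain².
    sample_every : int
        Output sampling stride in integration steps.
    """
    from .classical import beta as _beta

    if domain is None:
        domain = (D.z0, D.z1)
    z_lo, z_hi = domain
    if D.at((z_lo + z_hi) / 2) * dt > (z_hi - z_lo) ** 2 / 100:
        raise ValueError("dt too large for the domain")
    # fine lookup tables for drift and noise amplitude
    ztab = np.linspace(z_lo, z_hi, 2049)
    Dsp = CubicSpline(D.z, D.values)
    Dv = np.maximum(Dsp(ztab), 1e-12)
    Dp = Dsp(ztab, 1)
    b = _beta(T)
    if w is None:
        F = np.zeros_like(ztab)
    else:
        wsp = CubicSpline(w.z, w.values)
        F = -wsp(ztab, 1)
    drift_tab = (b * Dv * F + Dp) * dt
    sig_tab = np.sqrt(2 * Dv * dt)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(steps)
    out = np.empty(steps // sample_every)
    nout = _bd_loop(z_init, drift_tab, sig_tab, z_lo, z_hi,
                    ztab[1] - ztab[0], steps, sample_every, noise, out)
    return Trajectory(dt * sample_every, out[:nout],
                      meta={"kind": "brownian", "T": T, "dt": dt,
                            "seed": seed, "domain": list(domain)})


# ---------------------------------------------------------------------------
# Fractional Brownian motion
# ---------------------------------------------------------------------------

def fgn(H: float, n: int, rng) -> np.ndarray:
    """Unit-variance fractional Gaussian noise by circulant embedding.

    Exact covariance r(k) = ½(|k+1|^2H - 2|k|^2H + |k-1|^2H); falls back to
    a Cholesky factorization if the embedding is not non-negative definite
    (does not occur for H ∈ (0, 1) with this covariance).
    """
    if not 0 < H < 1:
        raise ValueError("H must lie in (0, 1)")
    k = np.arange(n, dtype=float)
    r = 0.5 * ((k + 1) ** (2 * H) - 2 * k ** (2 * H)
               + np.abs(k - 1) ** (2 * H))
    emb = np.concatenate([r, r[-2:0:-1]])
    lam = np.fft.rfft(emb).real
    if np.any(lam < -1e-9 * lam.max()):
        L = np.linalg.cholesky(
            0.5 * (np.abs(np.subtract.outer(k, k) + 1) ** (2 * H)
                   - 2 * np.abs(np.subtract.outer(k, k)) ** (2 * H)
                   + np.abs(np.subtract.outer(k, k) - 1) ** (2 * H)))
        return L @ rng.standard_normal(n)
    lam = np.maximum(lam, 0.0)
    m = emb.size
    zr = rng.standard_normal(lam.size)
    zi = rng.standard_normal(lam.size)
    spec = np.sqrt(lam / m) * (zr + 1j * zi)
    spec[0] = np.sqrt(lam[0] / m) * zr[0] * np.sqrt(2)
    if m % 2 == 0:
        spec[-1] = np.sqrt(lam[-1] / m) * zr[-1] * np.sqrt(2)
    x = np.fft.irfft(spec, n=m) * m / np.sqrt(2)
    return x[:n]


def fbm_trajectory(H: float, scale: float = 1.0, steps: int = 100_000,
                   dt: float = 1e-3, seed: int = 0,
                   domain=None) -> Trajectory:
    """Fractional Brownian motion: MSD(t) = scale² (t/dt)^{2H} dt-step units.

    ``scale`` is the per-step increment standard deviation (Å).  If a
    domain is given the path is folded back at the walls (reflection),
    emulating a confined permeant.
    """
    rng = np.random.default_rng(seed)
    inc = scale * fgn(H, steps, rng)
    z = np.concatenate([[0.0], np.cumsum(inc)])
    if domain is not None:
        z_lo, z_hi = domain
        L = z_hi - z_lo
        zz = np.mod(z - z_lo, 2 * L)
        z = z_lo + np.where(zz <= L, zz, 2 * L - zz)
    return Trajectory(dt, z, meta={"kind": "fbm", "H": H, "scale": scale,
                                   "seed": seed})


# ---------------------------------------------------------------------------
# Continuous-time random walk
# ---------------------------------------------------------------------------

def _ctrw_walk(alpha, jump_scale, time_scale, duration, dt, rng, z_init=0.0,
               domain=None):
    n_samp = int(round(duration / dt)) + 1
    t = 0.0
    # renewal times: Pareto waits, survival (t/tau0)^-alpha for alpha < 1;
    # the alpha -> 1 limit is taken as exponential waits (classical walk)
    waits = []
    while t < duration:
        if alpha >= 1.0:
            wtt = rng.exponential(time_scale)
        else:
            wtt = time_scale * rng.uniform() ** (-1.0 / alpha)
        waits.append(wtt)
        t += wtt
    waits = np.array(waits)
    times = np.cumsum(waits)
    jumps = jump_scale * rng.standard_normal(times.size)
    pos = z_init + np.concatenate([[0.0], np.cumsum(jumps)])
    # piecewise-constant position sampled on the uniform grid
    grid = dt * np.arange(n_samp)
    idx = np.searchsorted(times, grid, side="right")
    z = pos[idx]
    if domain is not None:
        z_lo, z_hi = domain
        L = z_hi - z_lo
        zz = np.mod(z - z_lo, 2 * L)
        z = z_lo + np.where(zz <= L, zz, 2 * L - zz)
    return z


def ctrw_trajectory(alpha: float, jump_scale: float = 1.0,
                    time_scale: float = 1e-3, duration: float = 10.0,
                    dt: float = 1e-3, seed: int = 0, z_init: float = 0.0,
                    domain=None) -> Trajectory:
    """Single CTRW path: Gaussian jumps at Pareto-tailed renewal times.

    Waiting times follow survival (t/τ₀)^(-α) for t > τ₀ (index α ∈ (0,1)),
    so the ensemble MSD grows as t^α for t ≫ τ₀.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    z = _ctrw_walk(alpha, jump_scale, time_scale, duration, dt, rng, z_init,
                   domain)
    return Trajectory(dt, z, meta={"kind": "ctrw", "alpha": alpha,
                                   "jump_scale": jump_scale,
                                   "time_scale": time_scale, "seed": seed})


def ctrw_ensemble(n_walkers: int, alpha: float, jump_scale: float = 1.0,
                  time_scale: float = 1e-3, duration: float = 0.1,
                  dt: float = 1e-3, seed: int = 0, z_init: float = 0.0,
                  domain=None) -> list[Trajectory]:
    """Ensemble of independent CTRW walkers started fresh at t = 0.

    CTRW statistics age: displacement distributions along one long path
    differ from the ensemble propagator.  Inference against the fractional
    equation therefore uses fresh-walker ensembles.
    """
    rng = np.random.default_rng(seed)
    z0s = np.broadcast_to(np.asarray(z_init, float), (n_walkers,)) \
        if np.ndim(z_init) == 0 else np.asarray(z_init, float)
    out = []
    for i in range(n_walkers):
        z = _ctrw_walk(alpha, jump_scale, time_scale, duration, dt, rng,
                       float(z0s[i]), domain)
        out.append(Trajectory(dt, z, meta={"kind": "ctrw", "alpha": alpha,
                                           "walker": i, "seed": seed}))
    return out


# ---------------------------------------------------------------------------
# Stratified windows
# ---------------------------------------------------------------------------

def synthetic_windows(true_w: Profile, n_windows: int = 9,
                      overlap: float = 5.0, samples_per_bin: float = 1000,
                      noise: float = 1.0, bin_width: float = 0.1,
                      seed: int = 0) -> list[GradientWindow]:
    """Noisy stratified-window gradients from a known PMF.

    The domain is tiled by ``n_windows`` equal windows overlapping
    sequentially by ``overlap`` Å (the default geometry: nine 15-Å windows
    overlapping by 5 Å over 90 Å).  Per-bin gradients are the true ∂w/∂z
    plus Gaussian noise of standard deviation noise/sqrt(count); counts are
    Poisson with the given mean (floored at 1).
    """
    rng = np.random.default_rng(seed)
    z_lo, z_hi = true_w.z0, true_w.z1
    span = z_hi - z_lo
    # snap the window length up to a bin multiple so the window grids stay
    # commensurate with the target grid; the last window is clipped to the
    # domain (the nominal geometry, e.g. nine 15-Å windows over 90 Å with
    # 5-Å overlaps, is slightly over-determined)
    L_raw = (span + (n_windows - 1) * overlap) / n_windows
    L = math.ceil(L_raw / bin_width - 1e-9) * bin_width
    step = L - overlap
    wsp = CubicSpline(true_w.z, true_w.values)
    windows = []
    for s in range(n_windows):
        a = z_lo + s * step
        b = min(a + L, z_hi)
        nb = int(round((b - a) / bin_width))
        centers = a + bin_width * (np.arange(nb) + 0.5)
        counts = np.maximum(rng.poisson(samples_per_bin, nb), 1).astype(float)
        g = wsp(centers, 1) + noise / np.sqrt(counts) * rng.standard_normal(nb)
        windows.append(GradientWindow(f"win{s}", a, b, bin_width, counts, g))
    return windows


# ---------------------------------------------------------------------------
# Sphere packings with planted cavities
# ---------------------------------------------------------------------------

class AtomicConfiguration:
    """Minimal periodic configuration: coordinates, types, radii, cell."""

    def __init__(self, coords, types, radii: dict, cell):
        self.coords = np.asarray(coords, dtype=float)
        self.types = list(types)
        self.radii = dict(radii)
        self.cell = np.asarray(cell, dtype=float)  # orthorhombic lengths
        if np.any(self.cell <= 0):
            raise ValueError("cell lengths must be positive")
        if any(r <= 0 for r in self.radii.values()):
            raise ValueError("radii must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def radius_of(self, i: int) -> float:
        try:
            return self.radii[self.types[i]]
        except KeyError:
            raise KeyError(f"no radius entry for atom type "
                           f"{self.types[i]!r}") from None


def packing_with_cavity(cell=(30.0, 30.0, 30.0), n_atoms: int = 1000,
                        radius: float = 1.2, cavity_center=None,
                        cavity_radius: float = 0.0, seed: int = 0,
                        probe_margin: float = 1.5, seal_cavity: bool = True,
                        max_tries: int = 2_000_000) -> AtomicConfiguration:
    """Random non-overlapping sphere packing avoiding an exclusion ball.

    Spheres of the given radius are inserted sequentially at uniform random
    positions under periodic minimum-image distance checks; positions whose
    center falls within ``cavity_radius + radius + probe_margin`` of the
    cavity center are rejected.  ``probe_margin`` should equal the probe
    radius later used for void detection, so that the *detected* cavity
    (after inflating atoms by the probe) retains the nominal radius.  The
    defaults give a dense packing whose background voids are much smaller
    than a planted cavity of a few Å.
    """
    cell = np.asarray(cell, float)
    rng = np.random.default_rng(seed)
    placed = np.empty((0, 3))
    tries = 0
    if cavity_center is not None and cavity_radius > 0 and seal_cavity:
        # seal the exclusion surface with a shell of atoms so the detected
        # void keeps the nominal cavity radius (an unsealed RSA boundary
        # lets the void bulge outward through inter-atom gaps)
        R_sh = cavity_radius + radius + probe_margin
        ctr = np.asarray(cavity_center, float)
        for _ in range(40_000):
            v = rng.standard_normal(3)
            p = ctr + R_sh * v / np.linalg.norm(v)
            p = np.mod(p, cell)
            if placed.shape[0]:
                d = placed - p
                d -= cell * np.rint(d / cell)
                if np.min(np.einsum("ij,ij->i", d, d)) < (2 * radius) ** 2:
                    continue
            placed = np.vstack([placed, p])
        n_atoms = max(n_atoms, placed.shape[0])
    while placed.shape[0] < n_atoms:
        if tries >= max_tries:
            raise RuntimeError(
                f"placed only {placed.shape[0]}/{n_atoms} spheres "
                f"after {max_tries} tries (density unachievable)")
        tries += 1
        p = rng.uniform(0, 1, 3) * cell
        if cavity_center is not None and cavity_radius > 0:
            d = p - np.asarray(cavity_center)
            d -= cell * np.rint(d / cell)
            if np.linalg.norm(d) < cavity_radius + radius + probe_margin:
                continue
        if placed.shape[0]:
            d = placed - p
            d -= cell * np.rint(d / cell)
            if np.min(np.einsum("ij,ij->i", d, d)) < (2 * radius) ** 2:
                continue
        placed = np.vstack([placed, p])
    return AtomicConfiguration(placed, ["X"] * n_atoms, {"X": radius}, cell)
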