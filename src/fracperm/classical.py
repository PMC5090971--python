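"""Crank–Nicolson solver for the classical Smoluchowski equation.

The equation evolved is

    ∂c/∂t = ∂z [ D(z) ( ∂z c - β F(z) c ) ],

for the concentration (probability density) c(z, t) of a permeant on an
inhomogeneous diffusivity D(z) and deterministic-force F(z) = -∂z w(z)
landscape, with either zero-flux (Robin) walls,

    D(a) ∂z c(a,t) - β D(a) F(a) c(a,t) = 0,

or fixed-concentration (Dirichlet) boundaries.

Discretization: flux-conservative finite volumes on a uniform grid with
half-width boundary cells; the half-node fluxes use midpoint D and F values
taken from the models' cubic interpolants and the exponentially-fitted
(Scharfetter–Gummel) drift-diffusion form

    J_{i+1/2} = (D/h) [ B(-x) c_i - B(x) c_{i+1} ],   x = β F h,

with B(x) = x/(e^x - 1), which reduces to central differencing for F = 0
and keeps the Boltzmann density exp(-βw) discretely stationary even for
steep landscapes.  Setting the wall flux to zero implements the Robin
condition and conserves the trapezoidal mass identically.  Time stepping is
Crank–Nicolson (second order, unconditionally stable); the tridiagonal
systems are solved by banded LU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import eigh_tridiagonal, solve_banded

KB = 0.0019872  # Boltzmann constant, kcal mol^-1 K^-1
DEFAULT_T = 308.0  # K, the bilayer simulation temperature

__all__ = [
    "KB", "DEFAULT_T", "beta", "SpatialGrid", "ClassicalModel",
    "ConcentrationState", "CrankNicolson", "ClassicalPropagator",
    "cn_step", "propagate_delta", "displacement_probability",
    "current_profile", "force_from_pmf",
]


def beta(T: float = DEFAULT_T) -> float:
    """Inverse thermal energy 1/(kB T) in mol/kcal."""
    return 1.0 / (KB * T)


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform solver grid on [a_lo, a_hi] with spacing h (Å)."""

    a_lo: float = -45.0
    a_hi: float = 45.0
    h: float = 0.5

    def __post_init__(self):
        if self.h <= 0 or self.a_hi <= self.a_lo:
            raise ValueError("degenerate grid")
        n = round((self.a_hi - self.a_lo) / self.h) + 1
        if abs(self.a_lo + (n - 1) * self.h - self.a_hi) > 1e-9:
            raise ValueError("h must divide the domain length")

    @property
    def n(self) -> int:
        return round((self.a_hi - self.a_lo) / self.h) + 1

    @property
    def z(self) -> np.ndarray:
        return self.a_lo + self.h * np.arange(self.n)

    @property
    def z_mid(self) -> np.ndarray:
        return self.z[:-1] + 0.5 * self.h

    @property
    def cell_widths(self) -> np.ndarray:
        """Finite-volume cell widths: h interior, h/2 at the walls."""
        w = np.full(self.n, self.h)
        w[0] = w[-1] = 0.5 * self.h
        return w

    def index_of(self, z: float) -> int:
        i = int(round((z - self.a_lo) / self.h))
        if i < 0 or i >= self.n:
            raise ValueError(f"z = {z} outside the domain")
        return i


def _bernoulli(x):
    """B(x) = x / (e^x - 1), evaluated stably (B(0) = 1)."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-8
    out[small] = 1.0 - 0.5 * x[small]
    xs = np.clip(x[~small], -700, 700)
    out[~small] = xs / np.expm1(xs)
    return out


_MID_MAPS: dict = {}


def _midpoint_matrix(grid: SpatialGrid) -> np.ndarray:
    """Linear map node values -> cubic-interpolant values at half nodes.

    CubicSpline is linear in its data, so the midpoint values of the
    interpolant are M @ nodes for a fixed matrix M; caching M makes repeated
    model evaluations (e.g. inside MH sampling) cheap.
    """
    key = (grid.n, round(grid.h, 12))
    M = _MID_MAPS.get(key)
    if M is None:
        z, zm = grid.z, grid.z_mid
        M = np.empty((zm.size, z.size))
        e = np.zeros(z.size)
        for j in range(z.size):
            e[j] = 1.0
            M[:, j] = CubicSpline(z, e)(zm)
            e[j] = 0.0
        _MID_MAPS[key] = M
    return M


class ClassicalModel:
    """Position-dependent diffusivity D(z) > 0 (Å²/ns) and force F(z).

    D is represented by a cubic interpolant with continuous first
    derivatives through the grid nodes, as required for evaluating the
    half-node fluxes.  F (kcal/mol/Å) may be given directly or derived from
    a PMF w(z) by centered differences at the nodes.
    """

    def __init__(self, grid: SpatialGrid, D_nodes, F_nodes=None, w_nodes=None,
                 T: float = DEFAULT_T):
        self.grid = grid
        self.D_nodes = np.asarray(D_nodes, dtype=float)
        if self.D_nodes.shape != (grid.n,):
            raise ValueError("D_nodes must match the grid")
        if np.any(self.D_nodes <= 0):
            raise ValueError("D must be positive everywhere")
        if F_nodes is None:
            if w_nodes is None:
                F_nodes = np.zeros(grid.n)
            else:
                F_nodes = force_from_pmf(np.asarray(w_nodes, float), grid.h)
        self.F_nodes = np.asarray(F_nodes, dtype=float)
        if self.F_nodes.shape != (grid.n,):
            raise ValueError("F_nodes must match the grid")
        self.T = T
        M = _midpoint_matrix(grid)
        self.D_mid = M @ self.D_nodes
        self.F_mid = M @ self.F_nodes
        if np.any(self.D_mid <= 0):
            raise ValueError("cubic interpolant of D undershoots zero "
                             "between nodes")

    @property
    def beta(self) -> float:
        return beta(self.T)

    def D(self, z):
        return CubicSpline(self.grid.z, self.D_nodes)(z)

    def operator_bands(self, bc="robin_zero_flux"):
        """Tridiagonal bands (lower, diag, upper) of the spatial operator.

        Row i of A gives dc_i/dt = (A c)_i.  For Dirichlet boundaries the
        first and last rows are zero so the boundary values stay fixed.
        """
        g = self.grid
        h, n = g.h, g.n
        a_half = self.D_mid / h**2                 # D_{i+1/2}/h²
        x = self.beta * self.F_mid * h             # cell Péclet number
        bm = a_half * _bernoulli(-x)               # weight of c_i  in J_{i+1/2}
        bp = a_half * _bernoulli(x)                # weight of c_{i+1}
        lower = np.zeros(n)
        diag = np.zeros(n)
        upper = np.zeros(n)
        # interior rows: -(J_{i+1/2} - J_{i-1/2})/h
        diag[1:-1] = -bm[1:] - bp[:-1]
        upper[1:-1] = bp[1:]
        lower[1:-1] = bm[:-1]
        if bc == "robin_zero_flux":
            # half-width wall cells, wall flux = 0
            diag[0] = -2 * bm[0]
            upper[0] = 2 * bp[0]
            diag[-1] = -2 * bp[-1]
            lower[-1] = 2 * bm[-1]
        elif bc == "dirichlet":
            pass  # zero rows: boundary values held fixed
        else:
            raise ValueError(f"unknown boundary condition {bc!r}")
        return lower, diag, upper


@dataclass
class ConcentrationState:
    """Discretized concentration c(z, t) with its boundary descriptor."""

    grid: SpatialGrid
    c: np.ndarray
    t: float = 0.0
    bc: str = "robin_zero_flux"

    def mass(self) -> float:
        """Trapezoidal mass ∫ c dz."""
        return float(np.trapezoid(self.c, dx=self.grid.h))


def force_from_pmf(w_nodes: np.ndarray, h: float) -> np.ndarray:
    """F = -∂w/∂z by centered differences (one-sided at the walls)."""
    F = np.empty_like(w_nodes)
    F[1:-1] = -(w_nodes[2:] - w_nodes[:-2]) / (2 * h)
    F[0] = -(w_nodes[1] - w_nodes[0]) / h
    F[-1] = -(w_nodes[-1] - w_nodes[-2]) / h
    return F


def _banded_matvec(lower, diag, upper, C):
    out = diag[:, None] * C
    out[:-1] += upper[:-1, None] * C[1:]
    out[1:] += lower[1:, None] * C[:-1]
    return out


class CrankNicolson:
    """Crank–Nicolson stepper (I - τ/2 A) c⁺ = (I + τ/2 A) c.

    Supports multiple concentration columns at once (shape (n, m)), which is
    how propagators for many initial nodes are evolved together.
    """

    def __init__(self, model: ClassicalModel, tau: float,
                 bc: str = "robin_zero_flux"):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.model = model
        self.tau = tau
        self.bc = bc
        lower, diag, upper = model.operator_bands(bc)
        self._bands = (lower, diag, upper)
        n = model.grid.n
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * tau * upper[:-1]
        ab[1, :] = 1.0 - 0.5 * tau * diag
        ab[2, :-1] = -0.5 * tau * lower[1:]
        self._lhs_ab = ab

    def step(self, C: np.ndarray) -> np.ndarray:
        lower, diag, upper = self._bands
        rhs = C + 0.5 * self.tau * _banded_matvec(lower, diag, upper, C)
        return solve_banded((1, 1), self._lhs_ab, rhs,
                            overwrite_ab=False, overwrite_b=True)


def cn_step(state: ConcentrationState, model: ClassicalModel,
            tau: float) -> ConcentrationState:
    """Advance the concentration by one Crank–Nicolson step of length τ (ns)."""
    stepper = CrankNicolson(model, tau, state.bc)
    c = stepper.step(state.c[:, None])[:, 0]
    return ConcentrationState(state.grid, c, state.t + tau, state.bc)


class ClassicalPropagator:
    """Single-source propagators of the classical equation, cached per node.

    The PDE solution from a delta at node i depends only on (i, model, lag),
    so it is computed once and reused for every trajectory segment starting
    at that node — the dominant cost saving in likelihood evaluation.
    """

    def __init__(self, model: ClassicalModel, tau: float = 5e-4,
                 bc: str = "robin_zero_flux"):
        self.model = model
        self.tau = tau
        self.bc = bc
        self._cache: dict = {}
        self._spectral = None

    def _spectral_parts(self):
        """Symmetrized eigendecomposition of the zero-flux operator.

        The scheme obeys detailed balance, so D = diag(s)⁻¹ A diag(s) is
        symmetric tridiagonal for s from the flux-ratio recursion; the
        Crank–Nicolson step matrix then shares eigenvectors with A and its
        repeated application reduces to a diagonal power — one
        eigendecomposition yields the propagator at every lag.
        """
        if self._spectral is None:
            lower, diag, upper = self.model.operator_bands(self.bc)
            u = upper[:-1]
            l = lower[1:]
            if np.any(u <= 0) or np.any(l <= 0):
                raise FloatingPointError("operator not symmetrizable")
            log_ratio = 0.5 * (np.log(l) - np.log(u))
            log_s = np.concatenate([[0.0], np.cumsum(log_ratio)])
            log_s -= log_s.mean()
            if np.max(np.abs(log_s)) > 300:  # overflow guard
                raise FloatingPointError("extreme force landscape")
            s = np.exp(log_s)
            e = np.sqrt(u * l)
            lam, V = eigh_tridiagonal(diag, e)
            self._spectral = (s, lam, V)
        return self._spectral

    def _evolve(self, nodes, lag):
        g = self.model.grid
        nsteps = max(1, int(np.ceil(lag / self.tau - 1e-12)))
        tau_last = lag - (nsteps - 1) * self.tau
        cw = g.cell_widths
        C = np.zeros((g.n, len(nodes)))
        for j, i in enumerate(nodes):
            C[i, j] = 1.0 / cw[i]
        if self.bc == "robin_zero_flux":
            try:
                s, lam, V = self._spectral_parts()
            except FloatingPointError:
                pass
            else:
                growth = ((1 + 0.5 * self.tau * lam)
                          / (1 - 0.5 * self.tau * lam)) ** (nsteps - 1)
                growth *= ((1 + 0.5 * tau_last * lam)
                           / (1 - 0.5 * tau_last * lam))
                Y = V.T @ (C / s[:, None])
                return s[:, None] * (V @ (growth[:, None] * Y))
        stepper = CrankNicolson(self.model, self.tau, self.bc)
        for _ in range(nsteps - 1):
            C = stepper.step(C)
        if abs(tau_last - self.tau) < 1e-15:
            C = stepper.step(C)
        else:  # shrink the final step to land exactly on the lag
            C = CrankNicolson(self.model, tau_last, self.bc).step(C)
        return C

    def matrix(self, nodes, lag: float) -> np.ndarray:
        """Columns c(·, lag) for deltas started at each node index."""
        key = round(lag, 12)
        per_lag = self._cache.setdefault(key, {})
        missing = [i for i in nodes if i not in per_lag]
        if missing:
            C = self._evolve(missing, lag)
            for j, i in enumerate(missing):
                per_lag[i] = C[:, j]
        return np.stack([per_lag[i] for i in nodes], axis=1)

    def propagate(self, z0: float, lag: float) -> ConcentrationState:
        if lag <= 0:
            raise ValueError("lag must be positive")
        i = self.model.grid.index_of(z0)
        c = self.matrix([i], lag)[:, 0]
        return ConcentrationState(self.model.grid, c.copy(), lag, self.bc)

    def displacement_probability(self, z0: float, z1: float,
                                 lag: float) -> float:
        """P(z0 -> nearest node to z1 | model) over the lag time.

        The density amplitude at the final node is multiplied by that node's
        finite-volume cell width, so the probabilities over all final nodes
        sum to one under zero-flux boundaries.
        """
        st = self.propagate(z0, lag)
        f = self.model.grid.index_of(z1)
        return float(st.c[f] * self.model.grid.cell_widths[f])


def propagate_delta(z0: float, lag: float, model: ClassicalModel,
                    tau: float = 5e-4,
                    bc: str = "robin_zero_flux") -> ConcentrationState:
    """Evolve a delta (density 1/cell width at the node nearest z0) to `lag`."""
    return ClassicalPropagator(model, tau, bc).propagate(z0, lag)


def displacement_probability(z0: float, z1: float, lag: float,
                             model: ClassicalModel, tau: float = 5e-4,
                             bc: str = "robin_zero_flux") -> float:
    return ClassicalPropagator(model, tau, bc).displacement_probability(
        z0, z1, lag)


def scheme_current(c: np.ndarray, model: ClassicalModel) -> np.ndarray:
    """Discrete half-node current of the finite-volume scheme.

    J_{i+1/2} = (D/h)[B(-x) c_i - B(x) c_{i+1}] with x = βFh.  At the
    discrete steady state this is constant in z to machine precision, which
    makes it the right quantity for steady-state flux detection.
    """
    g = model.grid
    x = model.beta * model.F_mid * g.h
    return (model.D_mid / g.h) * (_bernoulli(-x) * c[:-1]
                                  - _bernoulli(x) * c[1:])


def current_profile(state: ConcentrationState, model: ClassicalModel):
    """Particle current J(z) = -[D ∂z - β D F] c at the grid nodes.

    Centered differences in the interior, one-sided at the walls.  In a
    Dirichlet-driven steady state J is independent of z.
    """
    from .profiles import Profile

    g = state.grid
    if g.n != model.grid.n:
        raise ValueError("state and model grids differ")
    c = state.c
    h = g.h
    dc = np.empty_like(c)
    dc[1:-1] = (c[2:] - c[:-2]) / (2 * h)
    dc[0] = (c[1] - c[0]) / h
    dc[-1] = (c[-1] - c[-2]) / h
    J = -model.D_nodes * dc + model.beta * model.D_nodes * model.F_nodes * c
    return Profile(g.a_lo, h, J, "1/ns")
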