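"""Time-fractional Smoluchowski solver with position-dependent order.

The classical first-order time derivative is replaced by a Caputo
derivative of order α(z) ∈ (0, 1], and the diffusivity D(z) by the
fractional diffusivity K_α(z) with units Å²/ns^α:

    ∂^α(z) c / ∂t^α(z) = ∂z [ K_α(z) ( ∂z c - β F(z) c ) ].

The Caputo derivative is discretized by the L1 rule: at step m+1,

    ∂^α c ≈ (τ^-α / Γ(2-α)) Σ_{k=0}^{m} b_k (c^{m+1-k} - c^{m-k}),
    b_k = (k+1)^(1-α) - k^(1-α),

which carries memory of the whole solution history (cost O(n_steps²)).
The spatial operator is averaged Crank–Nicolson-fashion between steps m and
m+1.  Because the order field is position dependent, the memory weights and
the scale σ = Γ(2-α) τ^α are evaluated with each node's local α in that
node's row; for α ≡ 1 every b_k with k ≥ 1 vanishes and the scheme reduces
exactly to the classical Crank–Nicolson step.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.linalg import lu_factor, lu_solve, solve_banded

from .classical import (DEFAULT_T, ClassicalModel, ConcentrationState,
                        SpatialGrid, _banded_matvec)

__all__ = ["FractionalModel", "MemoryHistory", "caputo_weights",
           "FractionalStepper", "fractional_step", "fractional_propagator",
           "FractionalPropagator"]


def caputo_weights(alpha: float, n_steps: int) -> np.ndarray:
    """L1 Caputo weights b_k = (k+1)^(1-α) - k^(1-α), k = 0..n_steps-1.

    Positive, strictly decreasing, b_0 = 1; they telescope so that
    Σ_{k<n} b_k = n^(1-α).  For α = 1 all weights with k ≥ 1 vanish
    (memoryless classical limit).
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    k = np.arange(n_steps, dtype=float)
    b = (k + 1) ** (1 - alpha) - k ** (1 - alpha)
    if n_steps > 0:
        b[0] = 1.0  # 0^(1-α) = 0 also in the α = 1 limit (numpy's 0^0 = 1)
    return b


class FractionalModel(ClassicalModel):
    """α(z) and K_α(z) fields sharing the classical model's interpolants.

    ``D_nodes`` of the base class holds K_α at the nodes (Å²/ns^α); the
    spatial operator is identical to the classical one with K in place of D.
    """

    def __init__(self, grid: SpatialGrid, alpha_nodes, K_nodes, F_nodes=None,
                 w_nodes=None, T: float = DEFAULT_T):
        super().__init__(grid, K_nodes, F_nodes=F_nodes, w_nodes=w_nodes, T=T)
        self.alpha_nodes = np.asarray(alpha_nodes, dtype=float)
        if self.alpha_nodes.shape != (grid.n,):
            raise ValueError("alpha_nodes must match the grid")
        if np.any((self.alpha_nodes <= 0) | (self.alpha_nodes > 1)):
            raise ValueError("alpha must lie in (0, 1] at all nodes")

    @property
    def K_nodes(self):
        return self.D_nodes


class MemoryHistory:
    """Past solution increments and per-node weight cache for the L1 sum."""

    def __init__(self, model: FractionalModel, c0: np.ndarray, tau: float,
                 bc: str = "robin_zero_flux", capacity: int = 64):
        self.model = model
        self.tau = tau
        self.bc = bc
        c0 = np.atleast_2d(np.asarray(c0, float).T).T  # (n, m)
        self.c = c0.copy()
        self.t = 0.0
        self._m = 0  # completed steps
        n, width = self.c.shape
        self._D = np.empty((capacity, n, width))  # d^j = c^j - c^{j-1}
        a = model.alpha_nodes
        self._B = np.empty((capacity, n))  # rows: b_k per node, k = 1..
        self._alpha_is_one = bool(np.all(a == 1.0))

    @property
    def steps(self) -> int:
        return self._m

    def _grow(self):
        self._D = np.concatenate([self._D, np.empty_like(self._D)])
        self._B = np.concatenate([self._B, np.empty_like(self._B)])

    def weights(self, k: int) -> np.ndarray:
        """Per-node b_k row (k >= 1)."""
        a = self.model.alpha_nodes
        return (k + 1) ** (1 - a) - k ** (1 - a)

    def memory_term(self) -> np.ndarray:
        """Σ_{k=1..m} b_k (c^{m+1-k} - c^{m-k}), per node (vectorized)."""
        m = self._m
        if m == 0 or self._alpha_is_one:
            return np.zeros_like(self.c)
        # term k uses d^{m+1-k}: k=1 -> d^m (latest) ... k=m -> d^1
        return np.einsum("kn,knm->nm", self._B[:m], self._D[:m][::-1])

    def push(self, c_new: np.ndarray):
        if not self._alpha_is_one:
            if self._m >= self._D.shape[0]:
                self._grow()
            np.subtract(c_new, self.c, out=self._D[self._m])
            self._B[self._m] = self.weights(self._m + 1)
        self._m += 1
        self.c = c_new
        self.t += self.tau


class FractionalStepper:
    """Sweilam-type Crank–Nicolson stepper for the fractional equation.

    Per node i (σ_i = Γ(2-α_i) τ^{α_i}):

        c_i^{m+1} - (σ_i/2)(L c^{m+1})_i =
            c_i^m + (σ_i/2)(L c^m)_i - Σ_{k=1}^m b_{k,i}(c_i^{m+1-k} - c_i^{m-k})
    """

    def __init__(self, model: FractionalModel, tau: float,
                 bc: str = "robin_zero_flux"):
        if tau <= 0:
            raise ValueError("tau must be positive")
        self.model = model
        self.tau = tau
        self.bc = bc
        a = model.alpha_nodes
        gam = np.array([math.gamma(2 - ai) for ai in a])
        self.sigma = gam * tau ** a
        lower, diag, upper = model.operator_bands(bc)
        self._bands = (lower, diag, upper)
        n = model.grid.n
        s2 = 0.5 * self.sigma
        ab = np.zeros((3, n))
        ab[0, 1:] = -s2[:-1] * upper[:-1]
        ab[1, :] = 1.0 - s2 * diag
        ab[2, :-1] = -s2[1:] * lower[1:]
        self._lhs_ab = ab
        # the LHS matrix is constant across steps; factor it once
        dense = np.diag(ab[1])
        dense[np.arange(n - 1), np.arange(1, n)] = ab[0, 1:]
        dense[np.arange(1, n), np.arange(n - 1)] = ab[2, :-1]
        self._lu = lu_factor(dense, check_finite=False)

    def step(self, hist: MemoryHistory) -> np.ndarray:
        lower, diag, upper = self._bands
        C = hist.c
        rhs = (C + 0.5 * self.sigma[:, None]
               * _banded_matvec(lower, diag, upper, C)
               - hist.memory_term())
        c_new = lu_solve(self._lu, rhs, overwrite_b=True, check_finite=False)
        hist.push(c_new)
        return c_new


def fractional_step(history: MemoryHistory, model: FractionalModel,
                    tau: float) -> ConcentrationState:
    """Advance the fractional solution one step; returns the new state."""
    if abs(tau - history.tau) > 1e-15:
        raise ValueError("tau must match the history stepping")
    stepper = FractionalStepper(model, tau, history.bc)
    c = stepper.step(history)
    return ConcentrationState(model.grid, c[:, 0].copy(), history.t,
                              history.bc)


class FractionalPropagator:
    """Single-source fractional propagators, cached per initial node.

    The L1 memory weights require uniform steps, so the step is set to
    τ_eff = lag / ceil(lag/τ) ≤ τ rather than shrinking only the final one.
    """

    def __init__(self, model: FractionalModel, tau: float = 5e-4,
                 bc: str = "robin_zero_flux"):
        self.model = model
        self.tau = tau
        self.bc = bc
        self._cache: dict = {}

    def _evolve(self, nodes, lag, snapshots=None):
        g = self.model.grid
        nsteps = max(1, int(np.ceil(lag / self.tau - 1e-12)))
        tau_eff = lag / nsteps
        cw = g.cell_widths
        C = np.zeros((g.n, len(nodes)))
        for j, i in enumerate(nodes):
            C[i, j] = 1.0 / cw[i]
        hist = MemoryHistory(self.model, C, tau_eff, self.bc,
                             capacity=nsteps)
        stepper = FractionalStepper(self.model, tau_eff, self.bc)
        out = {}
        for s in range(1, nsteps + 1):
            stepper.step(hist)
            if snapshots and s in snapshots:
                out[s] = hist.c.copy()
        return hist.c, out

    def matrix(self, nodes, lag: float) -> np.ndarray:
        key = round(lag, 12)
        per_lag = self._cache.setdefault(key, {})
        missing = [i for i in nodes if i not in per_lag]
        if missing:
            C, _ = self._evolve(missing, lag)
            for j, i in enumerate(missing):
                per_lag[i] = C[:, j]
        return np.stack([per_lag[i] for i in nodes], axis=1)

    def matrices_multi(self, nodes, lags) -> dict:
        """Propagator matrices at several lags from one evolution.

        All lags must be integer multiples of the effective step for the
        longest lag; intermediate solutions are snapshotted in passing,
        which nearly halves the cost of multi-lag likelihoods.
        """
        lag_max = max(lags)
        nsteps = max(1, int(np.ceil(lag_max / self.tau - 1e-12)))
        tau_eff = lag_max / nsteps
        snap = {}
        for lag in lags:
            s = lag / tau_eff
            if abs(s - round(s)) > 1e-9:
                # incommensurate: fall back to separate evolutions
                return {lag: self.matrix(nodes, lag) for lag in lags}
            snap[int(round(s))] = lag
        _, out = self._evolve(list(nodes), lag_max,
                              snapshots=set(snap.keys()))
        return {snap[s]: C for s, C in out.items()}

    def propagate(self, z0: float, lag: float) -> ConcentrationState:
        if lag <= 0:
            raise ValueError("lag must be positive")
        i = self.model.grid.index_of(z0)
        c = self.matrix([i], lag)[:, 0]
        return ConcentrationState(self.model.grid, c.copy(), lag, self.bc)

    def displacement_probability(self, z0: float, z1: float,
                                 lag: float) -> float:
        st = self.propagate(z0, lag)
        f = self.model.grid.index_of(z1)
        return float(st.c[f] * self.model.grid.cell_widths[f])


def fractional_propagator(z0: float, lag: float, model: FractionalModel,
                          tau: float = 5e-4,
                          bc: str = "robin_zero_flux") -> ConcentrationState:
    """Solution at time `lag` from a delta at the node nearest z0."""
    return FractionalPropagator(model, tau, bc).propagate(z0, lag)
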