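"""Quasi-steady cellular pressure and pressure-driven movement rates.

The mechanics of the population rests on one constitutive picture: voxels
above one cell act as unit pressure sources, the pressure field ``p``
solves the discrete Poisson problem

    -L p = s(u)   on the populated voxels Omega_h,   p = 0 on dOmega_h,

with ``s(u_i) = 1`` iff ``u_i = 2`` (dead cells are not sources), and the
current over an edge is the integrated pressure gradient

    I_ij = (e_ij / d_ij) (p_i - p_j).

Positive currents convert to stochastic movement rates through three
conversion factors:

* ``D1`` — moves into *never-visited* empty voxels (fresh matrix),
* ``D2`` — moves into *previously visited* empty voxels,
* ``D3`` — "crowding" moves from a doubly occupied voxel into a singly
  occupied neighbour.

By the divergence theorem the total current over the free boundary equals
the number of enclosed sources, so with ``D2 = D3`` a cell in a single
interior source voxel is as likely to move as the population is to gain a
cell at its boundary.

Optional extensions implemented here: cell-cell adhesion as a negative
current correction, a chemotactic drift term inside the pressure solve
(pressure advected down a repellent gradient with sensitivity ``chi1``),
the analytic steady-state Slit concentration profile, and an active,
pressure-independent chemotactic current with affinity ``chi2``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .exceptions import ConfigurationError, NoFreeBoundaryError, SolverError
from .grid import Grid, LaplacianOperator
from .population_state import Event, PopulationState

__all__ = [
    "RateConstants", "EventSet", "PressureSolver",
    "compute_pressure", "edge_current", "enumerate_move_events",
    "adhesion_correction", "compute_pressure_with_drift",
    "slit_field", "active_drift_current", "drift_edge_currents",
]


@dataclass(frozen=True)
class RateConstants:
    """Conversion factors from unit edge current to event rate.

    All values are nonnegative and dimensionless per unit current (the
    model fixes no absolute time unit; rates inherit whatever unit the
    ``D``'s are given in).  ``alpha_adh`` is the adhesion constant and
    ``chi1`` / ``chi2`` the passive (pressure-drift) and active
    chemotactic sensitivities.
    """
    D1: float = 1.0
    D2: float = 1.0
    D3: float = 1.0
    alpha_adh: float = 0.0
    chi1: float = 0.0
    chi2: float = 0.0

    def __post_init__(self):
        for name in ("D1", "D2", "D3", "alpha_adh"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


class EventSet:
    """Enumerated discrete events with nonnegative rates.

    Zero-rate events are never stored; the total rate is cached.
    """

    def __init__(self, events=(), rates=()):
        self.events: list[Event] = []
        rlist = []
        for ev, r in zip(events, rates):
            if r < 0:
                raise ValueError(f"negative rate {r} for event {ev}")
            if r > 0:
                self.events.append(ev)
                rlist.append(float(r))
        self.rates = np.array(rlist, dtype=float)
        self.total = float(self.rates.sum())

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(zip(self.events, self.rates))

    def extend(self, other: "EventSet") -> "EventSet":
        merged = EventSet.__new__(EventSet)
        merged.events = self.events + other.events
        merged.rates = np.concatenate([self.rates, other.rates])
        merged.total = self.total + other.total
        return merged


class PressureSolver:
    """Direct sparse solver for the restricted Dirichlet pressure system.

    The linear system is restricted to the populated voxels (smallest
    well-posed system; the homogeneous Dirichlet data contribute exact
    zeros outside).  The LU factorization is cached and reused while the
    populated set is unchanged — crowding moves, proliferation and death
    change sources but not the domain, so re-solves are then a cheap
    triangular sweep.
    """

    def __init__(self, grid: Grid, L: LaplacianOperator):
        self.grid = grid
        self.L = L
        self._mask_key: bytes | None = None
        self._lu = None
        self._idx = None

    def solve(self, state: PopulationState) -> np.ndarray:
        return _solve_restricted(state, self.grid, self.L, cache=self)


def _solve_restricted(state, grid, L, cache=None):
    source = (state.u == 2).astype(float)
    if not source.any():
        # no overcrowded voxel: equilibrium, p identically zero
        return np.zeros(grid.n_voxels)
    occ = state.u != 0
    if occ.all():
        raise NoFreeBoundaryError(
            "populated region covers the whole grid; the Dirichlet "
            "pressure problem has no free boundary")
    idx = np.flatnonzero(occ)
    key = occ.tobytes()
    if cache is not None and cache._mask_key == key:
        lu = cache._lu
    else:
        A = (-L.matrix)[idx][:, idx].tocsc()
        try:
            lu = spla.splu(A)
        except RuntimeError as err:  # pragma: no cover - defensive
            raise SolverError(f"pressure system factorization failed: {err}")
        if cache is not None:
            cache._mask_key, cache._lu, cache._idx = key, lu, idx
    p = np.zeros(grid.n_voxels)
    p[idx] = lu.solve(source[idx])
    return p


def compute_pressure(state: PopulationState, grid: Grid,
                     L: LaplacianOperator) -> np.ndarray:
    """Solve the quasi-steady pressure problem for the current state.

    Returns the full-length pressure field: the solution of
    ``-L p = s(u)`` on the populated voxels with ``p = 0`` on the free
    boundary and on every voxel outside.  With no doubly occupied voxel
    the field is identically zero (mechanical equilibrium) and no solve is
    performed.  Raises :class:`NoFreeBoundaryError` if sources exist but
    the populated region covers the entire grid.
    """
    return _solve_restricted(state, grid, L)


def edge_current(p: np.ndarray, grid: Grid, i: int, j: int) -> float:
    """Pressure-driven current ``I_ij = (e_ij/d_ij)(p_i - p_j)`` over the
    edge between neighbour voxels ``i`` and ``j`` (antisymmetric in
    ``i, j``; raises ValueError for non-neighbours)."""
    m = grid.edge_id(i, j)
    w = grid.edge_measure[m] / grid.center_distance[m]
    return float(w * (p[i] - p[j]))


def adhesion_correction(state: PopulationState, grid: Grid, i: int, j: int,
                        alpha_adh: float) -> float:
    """Adhesion resistance for the move ``i -> j``.

    Sums, over populated neighbours ``k`` of ``i`` (other than ``j``), the
    bond term ``alpha * e_ik * min(0, r_ij . r_ik)`` with ``r`` unit
    centre-to-centre vectors, scaled by ``d_ij``; the result is ``<= 0``
    and is added to the current before rate conversion (the resulting rate
    is floored at zero: adhesion can stop a move but never reverse it).
    """
    if alpha_adh == 0.0:
        return 0.0
    m = grid.edge_id(i, j)
    rij = grid.unit_vector(i, j)
    acc = 0.0
    for k, mk in zip(grid.neighbours(i), grid.incident_edges(i)):
        if k == j or state.u[k] == 0:
            continue
        rik = grid.unit_vector(i, int(k))
        acc += alpha_adh * grid.edge_measure[mk] * min(0.0, float(rij @ rik))
    return float(grid.center_distance[m] * acc)


def enumerate_move_events(state: PopulationState, grid: Grid, p: np.ndarray,
                          constants: RateConstants,
                          extra_edge_current: np.ndarray | None = None
                          ) -> EventSet:
    """Enumerate all pressure-driven movement events and their rates.

    For every ordered neighbour pair ``(i, j)`` with positive total
    current (pressure current plus, optionally, a per-edge extra current
    such as active chemotaxis, given in the orientation of
    ``grid.edges``):

    * ``u_i >= 1`` and ``u_j = 0``: rate ``D1 * I`` if ``j`` was never
      visited, else ``D2 * I``;
    * ``u_i = 2`` and ``u_j = 1``: crowding, rate ``D3 * I``.

    Voxels holding a dead cell (``u = -1``) or at capacity are never
    destinations; dead cells never move.  With ``alpha_adh > 0`` the
    adhesion correction is added to each candidate current and the rate is
    floored at zero.
    """
    i, j = grid.edges[:, 0], grid.edges[:, 1]
    I_fwd = grid.weights * (p[i] - p[j])
    if extra_edge_current is not None:
        I_fwd = I_fwd + extra_edge_current
    src = np.concatenate([i, j])
    dst = np.concatenate([j, i])
    cur = np.concatenate([I_fwd, -I_fwd])

    u = state.u
    us, ud = u[src], u[dst]
    into_empty = (cur > 0) & (us >= 1) & (ud == 0)
    crowding = (cur > 0) & (us == 2) & (ud == 1)

    events, rates = [], []
    alpha = constants.alpha_adh
    for mask, factor in ((into_empty, None), (crowding, constants.D3)):
        for k in np.flatnonzero(mask):
            a, b = int(src[k]), int(dst[k])
            c = float(cur[k])
            if alpha > 0.0:
                c += adhesion_correction(state, grid, a, b, alpha)
                if c <= 0.0:
                    continue
            if factor is None:
                D = constants.D2 if state.visited[b] else constants.D1
            else:
                D = factor
            events.append(Event("move", a, b))
            rates.append(D * c)
    return EventSet(events, rates)


def compute_pressure_with_drift(state: PopulationState, grid: Grid,
                                L: LaplacianOperator, S: np.ndarray,
                                chi1: float) -> np.ndarray:
    """Pressure solve with a chemotactic drift term.

    Solves the discrete form of ``-lap p = div(p * chi1 * grad S) + s(u)``
    on the populated voxels with zero Dirichlet data on the free boundary.
    The edge flux is discretized as

        F_ij = (e_ij/d_ij) [ (p_i - p_j) + chi1 * pbar_ij * (S_i - S_j) ]

    with ``pbar_ij`` the arithmetic edge average of ``p`` (central,
    second-order), which yields a linear — generally nonsymmetric — system
    in ``p``.  Reduces exactly to :func:`compute_pressure` when
    ``chi1 = 0`` or ``S`` is constant.
    """
    S = np.asarray(S, dtype=float)
    source = (state.u == 2).astype(float)
    if not source.any():
        return np.zeros(grid.n_voxels)
    occ = state.u != 0
    if occ.all():
        raise NoFreeBoundaryError(
            "populated region covers the whole grid; the Dirichlet "
            "pressure problem has no free boundary")
    n = grid.n_voxels
    i, j = grid.edges[:, 0], grid.edges[:, 1]
    w = grid.weights
    dS = chi1 * (S[i] - S[j])
    # flux i->j: w*[(p_i - p_j) + dS*(p_i + p_j)/2]; assemble divergence rows
    rows = np.concatenate([i, i, j, j])
    cols = np.concatenate([i, j, j, i])
    vals = np.concatenate([
        w * (1.0 + dS / 2.0),    # d(F_ij)/d p_i at row i
        w * (-1.0 + dS / 2.0),   # d(F_ij)/d p_j at row i
        w * (1.0 - dS / 2.0),    # d(F_ji)/d p_j at row j
        w * (-1.0 - dS / 2.0),   # d(F_ji)/d p_i at row j
    ])
    A = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    idx = np.flatnonzero(occ)
    A_occ = A[idx][:, idx].tocsc()
    try:
        lu = spla.splu(A_occ)
        p_occ = lu.solve(source[idx])
    except RuntimeError as err:
        raise SolverError(
            "drift-modified pressure system is singular for chi1="
            f"{chi1} on {idx.size} populated voxels: {err}") from err
    if not np.all(np.isfinite(p_occ)):
        raise SolverError(
            f"drift-modified pressure solve returned non-finite values "
            f"(chi1={chi1}, {idx.size} populated voxels)")
    p = np.zeros(n)
    p[idx] = p_occ
    return p


def slit_field(grid: Grid, D_S: float, k: float, Q: float,
               X_s: float) -> np.ndarray:
    """Steady-state concentration of a line-sourced, degraded diffusible
    chemical (Slit).

    The balance ``0 = D_S lap S - k S + Q delta(x1 - X_s)`` on the plane
    has the closed-form solution

        S(x1, x2) = Q / (2 sqrt(k D_S)) * exp(-sqrt(k/D_S) |x1 - X_s|),

    independent of ``x2`` and maximal on the source line.  Evaluated at
    the voxel centres.
    """
    if D_S <= 0 or k <= 0 or Q <= 0:
        raise ConfigurationError("D_S, k and Q must be positive")
    x1 = grid.centers[:, 0]
    return (Q / (2.0 * np.sqrt(k * D_S))
            * np.exp(-np.sqrt(k / D_S) * np.abs(x1 - X_s)))


def active_drift_current(S: np.ndarray, grid: Grid, i: int, j: int,
                         chi2: float) -> float:
    """Active (pressure-independent) chemotactic current
    ``chi2 * (e_ij/d_ij) (S_i - S_j)`` for the move ``i -> j``; positive
    values are down-gradient moves.  Combined additively with the
    pressure-driven current before rate classification."""
    m = grid.edge_id(i, j)
    w = grid.edge_measure[m] / grid.center_distance[m]
    return float(chi2 * w * (S[i] - S[j]))


def drift_edge_currents(p: np.ndarray, S: np.ndarray, grid: Grid,
                        chi1: float, chi2: float) -> np.ndarray:
    """Per-edge chemotactic current contributions, oriented along
    ``grid.edges`` (row ``(i, j)`` means the ``i -> j`` direction).

    Combines the passive drift part of the flux,
    ``chi1 * pbar_ij * (S_i - S_j)``, with the active current
    ``chi2 * (S_i - S_j)``, both scaled by the edge weight.  Adding the
    result to the plain pressure current reconstructs the full flux of the
    drift-modified problem, so the boundary-current/source balance is
    preserved.
    """
    i, j = grid.edges[:, 0], grid.edges[:, 1]
    pbar = 0.5 * (p[i] + p[j])
    return grid.weights * (S[i] - S[j]) * (chi1 * pbar + chi2)
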