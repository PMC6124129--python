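"""Continuous-time event loop.

The simulation is an exact continuous-time Markov chain driven by the
Gillespie direct method: given the current state, all event rates are
enumerated, the waiting time to the next event is exponential at the
total rate, and the event itself is drawn proportionally to its rate.
Between events, processes local to each cell (intracellular ODEs) are
integrated deterministically — the mechanics rates do not read the
internal states, so this one-way coupling is exact.

Rates are recomputed from a fresh pressure solve after every applied
event (no stale-rate reuse); the restricted LU factorization is reused
whenever the populated voxel set is unchanged, which it is for crowding
moves, proliferation, and death.

Randomness comes from a single :class:`numpy.random.Generator` per run,
seeded from the configuration; identical seed and configuration give a
bit-identical trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import SolverError
from .grid import Grid, LaplacianOperator, assemble_laplacian
from .mechanics import (EventSet, PressureSolver, RateConstants,
                        enumerate_move_events)
from .population_state import Event, PopulationState

__all__ = ["Model", "Snapshot", "Trajectory", "sample_next_event",
           "advance_local_processes", "run_loop", "run_simulation"]


def sample_next_event(events: EventSet, rng: np.random.Generator):
    """Gillespie direct method: draw ``(tau, event)``.

    ``tau`` is exponential with rate equal to the total event rate and the
    event is chosen with probability proportional to its rate.  With no
    events, returns ``(inf, None)`` (absorbing state).
    """
    R = events.total
    if R < 0 or np.any(events.rates < 0):  # defensive: EventSet forbids this
        raise SolverError("negative rate in event set")
    if R == 0.0 or len(events) == 0:
        return math.inf, None
    tau = rng.exponential(1.0 / R)
    pick = rng.random() * R
    k = int(np.searchsorted(np.cumsum(events.rates), pick, side="right"))
    k = min(k, len(events) - 1)
    return tau, events.events[k]


def advance_local_processes(state: PopulationState, dt: float, rhs,
                            rtol: float = 1e-6, atol: float = 1e-9) -> PopulationState:
    """Integrate per-cell internal states forward by ``dt``.

    ``rhs(t, y)`` receives the stacked internal-state vector of all living
    cells in increasing id order and returns its derivative.  Mechanics
    state (occupancy, visited flags) is untouched; a ``None`` rhs or zero
    ``dt`` is a no-op.  Integration failures raise :class:`SolverError`
    with the simulation time.
    """
    if rhs is None or dt == 0.0:
        return state
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    cells = [c for c in state.cells.values()
             if c.alive and c.internal_state is not None]
    if not cells:
        return state
    y0 = np.concatenate([c.internal_state for c in cells])
    sol = solve_ivp(rhs, (0.0, dt), y0, method="RK45", rtol=rtol, atol=atol)
    if not sol.success:
        raise SolverError(
            f"internal-state integration failed at t={state.t} over "
            f"dt={dt} ({len(cells)} cells): {sol.message}")
    y = sol.y[:, -1]
    k = 0
    for c in cells:
        m = c.internal_state.size
        c.internal_state[:] = y[k:k + m]
        k += m
    return state


@dataclass
class Snapshot:
    """State recorded at one scheduled output time."""
    t: float
    u: np.ndarray
    visited: np.ndarray
    fields: dict
    internal: dict  # cell id -> internal state copy
    cells: dict = field(default_factory=dict)  # cell id -> voxel


@dataclass
class Trajectory:
    snapshots: list = field(default_factory=list)
    events: list = field(default_factory=list)  # (t, kind, i, j, cell_id)
    state: PopulationState | None = None

    @property
    def n_events(self) -> int:
        return len(self.events)


class Model:
    """Hook points composing the generic loop with model-specific physics.

    The base model is pure pressure-driven mechanics.  Subclasses may add
    scalar fields (oxygen, chemoattractants), extra per-edge currents,
    non-movement events (proliferation, death, degradation), an
    intracellular ODE right-hand side, and a termination predicate.
    """

    def __init__(self, constants: RateConstants):
        self.constants = constants

    def fields(self, state: PopulationState, grid: Grid,
               solver: PressureSolver) -> dict:
        """Solved scalar fields for the current state (at least
        ``pressure``)."""
        return {"pressure": solver.solve(state)}

    def extra_edge_current(self, state, grid, fields) -> np.ndarray | None:
        """Optional per-edge current added before rate classification
        (oriented along ``grid.edges``)."""
        return None

    def extra_events(self, state, grid, fields) -> EventSet:
        """Model-specific non-movement events."""
        return EventSet()

    def all_events(self, state, grid, fields) -> EventSet:
        moves = enumerate_move_events(
            state, grid, fields["pressure"], self.constants,
            extra_edge_current=self.extra_edge_current(state, grid, fields))
        return moves.extend(self.extra_events(state, grid, fields))

    def ode_rhs(self, state, grid):
        """Right-hand side for the stacked internal states, or ``None``."""
        return None

    def notify(self, state, event) -> None:
        """Called after each applied event (cache invalidation hook)."""

    def finished(self, state: PopulationState) -> bool:
        return False


def _resolve_cell(state: PopulationState, event: Event,
                  rng: np.random.Generator) -> Event:
    """Fill in the moving cell id: chosen uniformly at random among the
    source voxel's living cells (cells are mechanically indistinguishable;
    identity only matters for internal ODE state)."""
    if event.kind != "move" or event.cell_id >= 0:
        return event
    living = state.living_in(event.i)
    cid = living[0] if len(living) == 1 else living[int(rng.integers(len(living)))]
    return event._replace(cell_id=cid)


def run_loop(model: Model, state: PopulationState, grid: Grid,
             rng: np.random.Generator, *, t_end: float = math.inf,
             snapshot_times=(), L: LaplacianOperator | None = None,
             max_events: int | None = None) -> Trajectory:
    """Run the event loop until the horizon, the model's termination
    condition, or absorption (no events and no local processes).

    Snapshots are written at the requested times with internal ODE states
    advanced to the snapshot clock first, so recorded states are
    synchronous.  The final state is always appended as a snapshot.
    """
    if L is None:
        L = assemble_laplacian(grid)
    solver = PressureSolver(grid, L)
    traj = Trajectory(state=state)
    schedule = sorted(float(s) for s in snapshot_times)
    si = 0

    def take_snapshot(fields):
        traj.snapshots.append(Snapshot(
            t=state.t, u=state.u.copy(), visited=state.visited.copy(),
            fields={k: v.copy() for k, v in fields.items()},
            internal={c.id: c.internal_state.copy()
                      for c in state.cells.values()
                      if c.alive and c.internal_state is not None},
            cells={c.id: c.voxel for c in state.cells.values() if c.alive}))

    absorbed = False
    while True:
        fields = model.fields(state, grid, solver)
        rhs = model.ode_rhs(state, grid)
        events = model.all_events(state, grid, fields)
        tau, event = sample_next_event(events, rng)
        t_event = state.t + tau

        # emit snapshots falling before the next event (or the horizon)
        while si < len(schedule) and schedule[si] <= min(t_event, t_end):
            advance_local_processes(state, schedule[si] - state.t, rhs)
            state.t = schedule[si]
            take_snapshot(fields)
            si += 1

        if event is None and rhs is None:
            absorbed = True
            break  # absorbing state, nothing evolves any more
        if t_event > t_end:
            if rhs is not None and t_end < math.inf:
                advance_local_processes(state, t_end - state.t, rhs)
                state.t = t_end
            break

        advance_local_processes(state, t_event - state.t, rhs)
        state.t = t_event
        event = _resolve_cell(state, event, rng)
        state.apply_event(event)
        model.notify(state, event)
        traj.events.append((state.t, event.kind, event.i, event.j,
                            event.cell_id))
        if model.finished(state):
            break
        if max_events is not None and len(traj.events) >= max_events:
            break

    final_fields = model.fields(state, grid, solver)
    if absorbed:
        # the state is constant forever: remaining scheduled snapshots
        # within the horizon simply repeat it at their nominal times
        while si < len(schedule) and schedule[si] <= t_end:
            state.t = schedule[si]
            take_snapshot(final_fields)
            si += 1
    take_snapshot(final_fields)
    return traj


def run_simulation(config) -> Trajectory:
    """Run the experiment described by ``config`` (one of the experiment
    configuration dataclasses) and return its trajectory.  Thin dispatcher
    over :mod:`dlcm.experiments`."""
    from . import experiments

    return experiments.run(config)
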