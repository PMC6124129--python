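"""Discrete cell population state and event application.

Each voxel holds ``u_i`` cells with ``u_i`` in ``{-1, 0, 1, 2}``:
``0`` empty, ``1``/``2`` one or two living cells (2 is the carrying
capacity used throughout), and ``-1`` a single dead cell (tumour model
only; dead cells occupy their voxel and block movement until they
degrade).  A boolean ``visited`` flag records whether a voxel has ever
contained a living cell; it never reverts, and it is what distinguishes
the slow "fresh matrix" movement rate from the fast "previously occupied"
one in the mechanics.

Cells carry a unique integer id (never reused within a run) and an
optional internal state vector used by coupled intracellular ODE models
(e.g. Notch/Delta levels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .exceptions import ConfigurationError, IllegalEventError
from .grid import Grid

__all__ = ["Cell", "Event", "PopulationState", "initialize_state",
           "active_domain"]

CARRYING_CAPACITY = 2


class Event(NamedTuple):
    """A discrete event.

    ``kind`` is one of ``move``, ``proliferate``, ``die``, ``degrade``;
    ``i`` is the source voxel, ``j`` the destination voxel (moves only,
    else ``-1``) and ``cell_id`` identifies the moving cell (resolved by
    the engine just before application; ``-1`` means unresolved).
    """
    kind: str
    i: int
    j: int = -1
    cell_id: int = -1


@dataclass
class Cell:
    id: int
    voxel: int
    alive: bool = True
    internal_state: np.ndarray | None = None


class PopulationState:
    """Occupancy, cell registry and bookkeeping for one simulation run."""

    def __init__(self, n_voxels: int):
        self.u = np.zeros(n_voxels, dtype=np.int8)
        self.visited = np.zeros(n_voxels, dtype=bool)
        self.cells: dict[int, Cell] = {}
        self.t: float = 0.0
        self._voxel_living: list[list[int]] = [[] for _ in range(n_voxels)]
        self._voxel_dead: dict[int, int] = {}
        self._next_id: int = 0

    # -- queries ---------------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return self.u.shape[0]

    @property
    def n_living(self) -> int:
        return int(np.sum(np.maximum(self.u, 0)))

    def living_in(self, i: int) -> list[int]:
        """Ids of living cells currently in voxel ``i``."""
        return self._voxel_living[i]

    def living_cells(self) -> list[Cell]:
        """All living cells, in increasing id order."""
        return [c for c in self.cells.values() if c.alive]

    def dead_voxels(self) -> list[int]:
        return sorted(self._voxel_dead)

    # -- construction ----------------------------------------------------

    def add_cell(self, voxel: int,
                 internal_state: np.ndarray | None = None) -> Cell:
        if self.u[voxel] >= CARRYING_CAPACITY:
            raise IllegalEventError(f"voxel {voxel} is at carrying capacity")
        if self.u[voxel] < 0:
            raise IllegalEventError(f"voxel {voxel} holds a dead cell")
        cell = Cell(id=self._next_id, voxel=voxel,
                    internal_state=None if internal_state is None
                    else np.asarray(internal_state, dtype=float).copy())
        self._next_id += 1
        self.cells[cell.id] = cell
        self._voxel_living[voxel].append(cell.id)
        self.u[voxel] += 1
        self.visited[voxel] = True
        return cell

    # -- event application -----------------------------------------------

    def apply_event(self, event: Event) -> None:
        """Apply one discrete event atomically.

        Preconditions are checked strictly: a violated precondition raises
        :class:`IllegalEventError`, signalling an engine bug (illegal
        events are never silently ignored).
        """
        if event.kind == "move":
            self._apply_move(event)
        elif event.kind == "proliferate":
            self._apply_proliferate(event)
        elif event.kind == "die":
            self._apply_die(event)
        elif event.kind == "degrade":
            self._apply_degrade(event)
        else:
            raise IllegalEventError(f"unknown event kind {event.kind!r}")

    def _apply_move(self, event: Event) -> None:
        i, j = event.i, event.j
        ui, uj = int(self.u[i]), int(self.u[j])
        if not (ui >= 1 and uj in (0, 1) and uj < ui):
            raise IllegalEventError(
                f"illegal move {i}->{j} with u=({ui},{uj})")
        cid = event.cell_id
        if cid not in self._voxel_living[i]:
            raise IllegalEventError(
                f"cell {cid} is not a living occupant of voxel {i}")
        self._voxel_living[i].remove(cid)
        self._voxel_living[j].append(cid)
        self.cells[cid].voxel = j
        self.u[i] = ui - 1
        self.u[j] = uj + 1
        self.visited[j] = True

    def _apply_proliferate(self, event: Event) -> None:
        i = event.i
        if int(self.u[i]) != 1:
            raise IllegalEventError(
                f"proliferation requires u_i = 1, got u[{i}] = {self.u[i]}")
        mother = self.cells[self._voxel_living[i][0]]
        self.add_cell(i, internal_state=mother.internal_state)

    def _apply_die(self, event: Event) -> None:
        i = event.i
        if int(self.u[i]) != 1:
            raise IllegalEventError(
                f"death requires exactly one living cell, got u[{i}] = {self.u[i]}")
        cid = self._voxel_living[i][0]
        self._voxel_living[i] = []
        cell = self.cells[cid]
        cell.alive = False
        self._voxel_dead[i] = cid
        self.u[i] = -1

    def _apply_degrade(self, event: Event) -> None:
        i = event.i
        if int(self.u[i]) != -1:
            raise IllegalEventError(
                f"degradation requires a dead cell, got u[{i}] = {self.u[i]}")
        cid = self._voxel_dead.pop(i)
        del self.cells[cid]
        self.u[i] = 0

    # -- invariants --------------------------------------------------------

    def check_consistency(self) -> None:
        """Verify the occupancy/registry invariants; raise AssertionError
        on any violation.  Intended for tests and debug runs."""
        n_reg = 0
        for i in range(self.n_voxels):
            ui = int(self.u[i])
            living = self._voxel_living[i]
            assert -1 <= ui <= CARRYING_CAPACITY, f"u[{i}] = {ui} out of range"
            if ui >= 0:
                assert len(living) == ui, (
                    f"voxel {i}: u={ui} but {len(living)} living cells")
                assert i not in self._voxel_dead
            else:
                assert not living and i in self._voxel_dead
            if ui != 0:
                assert self.visited[i], f"occupied voxel {i} not visited"
            n_reg += len(living)
        assert n_reg == sum(1 for c in self.cells.values() if c.alive)
        for cid, cell in self.cells.items():
            assert cell.id == cid
            if cell.alive:
                assert cid in self._voxel_living[cell.voxel]


def initialize_state(grid: Grid, occupancy_map,
                     internal_state_init=None) -> PopulationState:
    """Create a population state from an occupancy map.

    Parameters
    ----------
    grid : Grid
    occupancy_map : mapping voxel -> count, or (N,) array of counts
        Counts must lie in ``{0, 1, 2}``.
    internal_state_init : None, vector, or callable
        Per-cell internal state: ``None`` for mechanics-only runs, a fixed
        vector copied into every cell, or a callable ``f(k) -> vector``
        evaluated per created cell (``k`` the cell's id).

    The registry is made consistent with the map, ``visited`` is set
    exactly where ``u != 0`` and the clock starts at ``t = 0``.
    """
    state = PopulationState(grid.n_voxels)
    if isinstance(occupancy_map, dict):
        occ = np.zeros(grid.n_voxels, dtype=np.int64)
        for i, c in occupancy_map.items():
            occ[int(i)] = int(c)
    else:
        occ = np.asarray(occupancy_map, dtype=np.int64)
        if occ.shape != (grid.n_voxels,):
            raise ConfigurationError(
                f"occupancy map has shape {occ.shape}, "
                f"expected ({grid.n_voxels},)")
    if np.any((occ < 0) | (occ > CARRYING_CAPACITY)):
        raise ConfigurationError(
            f"initial occupancy must lie in {{0, 1, {CARRYING_CAPACITY}}}")
    for i in np.flatnonzero(occ):
        for _ in range(int(occ[i])):
            if internal_state_init is None:
                init = None
            elif callable(internal_state_init):
                init = internal_state_init(state._next_id)
            else:
                init = internal_state_init
            state.add_cell(int(i), internal_state=init)
    return state


def active_domain(state: PopulationState, grid: Grid):
    """The populated voxel set and its free boundary.

    Returns ``(omega, boundary)``: ``omega`` are the voxels with
    ``u != 0`` (dead cells occupy their voxel) and ``boundary`` the empty
    voxels edge-adjacent to ``omega`` — the moving free boundary where the
    pressure is pinned to zero.  Both are sorted integer arrays and
    mutually disjoint.
    """
    occ = state.u != 0
    omega = np.flatnonzero(occ)
    i, j = grid.edges[:, 0], grid.edges[:, 1]
    touch = np.zeros(grid.n_voxels, dtype=bool)
    m = occ[i] & ~occ[j]
    touch[j[m]] = True
    m = occ[j] & ~occ[i]
    touch[i[m]] = True
    return omega, np.flatnonzero(touch)
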