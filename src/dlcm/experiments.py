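"""The four case-study experiments, as configured reproducible pipelines.

* **Relaxation** — cells forced into a square block at double occupancy
  relax to a round colony; averaging many trials quantifies grid
  (an)isotropy.
* **Slit chemo-repulsion** — a circular explant of neurons responds to the
  steady concentration profile of the diffusible repellent Slit through
  both a drift term in the pressure equation (sensitivity ``chi1``) and an
  active down-gradient current (affinity ``chi2``).
* **Delta–Notch on a growing tissue** — lateral-inhibition ODEs per cell,
  integrated between proliferation and movement events on a hexagonal
  grid until the population reaches a target size.
* **Avascular tumour** — oxygen diffuses in from the fixed outer boundary
  and is consumed by living cells; oxygen thresholds gate proliferation
  and death, dead cells degrade, and the colony develops proliferating,
  quiescent and necrotic regions.

Each experiment is reproducible from ``(config, seed)``; multi-trial
experiments draw independent child seeds from a single seed sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .engine import Model, run_loop
from .exceptions import ConfigurationError
from .grid import Grid, LaplacianOperator, assemble_laplacian, \
    build_structured_grid
from .mechanics import (EventSet, RateConstants, compute_pressure_with_drift,
                        drift_edge_currents, slit_field)
from .population_state import Event, PopulationState, initialize_state

__all__ = [
    "RelaxationConfig", "SlitConfig", "NotchConfig", "TumourConfig",
    "DeltaNotchParams", "TumourParams", "TrialResult",
    "relaxation_experiment", "slit_experiment", "delta_notch_experiment",
    "tumour_experiment", "delta_notch_rhs", "make_delta_notch_rhs",
    "tumour_oxygen", "tumour_events", "OxygenSolver",
    "square_block", "circular_region", "run",
]


# ---------------------------------------------------------------------------
# occupancy helpers

def square_block(grid: Grid, side: int, value: int = 2) -> np.ndarray:
    """Occupancy array with a centred square (2D) or cubic (3D) block of
    ``side`` voxels per axis at occupancy ``value``.

    On Cartesian grids the block is exact in index space; on other grids
    it is the set of voxels whose centres fall in the square of side
    ``side * h`` around the domain centre.
    """
    occ = np.zeros(grid.n_voxels, dtype=np.int64)
    if grid.kind.startswith("cartesian"):
        extent = grid.shape
        idx = np.arange(grid.n_voxels)
        coords = []
        stride = 1
        for n_axis in extent:
            coords.append((idx // stride) % n_axis)
            stride *= n_axis
        mask = np.ones(grid.n_voxels, dtype=bool)
        for c, n_axis in zip(coords, extent):
            lo = (n_axis - side) // 2
            mask &= (c >= lo) & (c < lo + side)
    else:
        c = grid.centers.mean(axis=0)
        half = side * grid.h / 2.0 + 1e-9
        mask = np.all(np.abs(grid.centers - c) <= half, axis=1)
    occ[mask] = value
    return occ


def circular_region(grid: Grid, radius: float, center=None,
                    value: int = 2) -> np.ndarray:
    """Occupancy array for the voxels whose centres lie within ``radius``
    of ``center`` (domain centre by default)."""
    c = grid.centers.mean(axis=0) if center is None else np.asarray(center)
    mask = np.linalg.norm(grid.centers - c, axis=1) <= radius + 1e-9
    occ = np.zeros(grid.n_voxels, dtype=np.int64)
    occ[mask] = value
    return occ


def _centered_origin(extent, h):
    return tuple(-(n - 1) * h / 2.0 for n in extent)


def _validate_common(cfg):
    for name in ("D1", "D2", "D3"):
        if getattr(cfg, name) < 0:
            raise ConfigurationError(f"{name} must be >= 0, got "
                                     f"{getattr(cfg, name)}")
    if cfg.h <= 0:
        raise ConfigurationError(f"h must be positive, got {cfg.h}")
    if getattr(cfg, "trials", 1) < 1:
        raise ConfigurationError("trials must be >= 1")
    if cfg.t_end <= 0:
        raise ConfigurationError("t_end must be positive")
    if any(s < 0 for s in cfg.snapshot_times):
        raise ConfigurationError("snapshot times must be >= 0")


# ---------------------------------------------------------------------------
# relaxation

@dataclass
class RelaxationConfig:
    """Square-block relaxation experiment (grid-artefact test)."""
    grid_kind: str = "cartesian2d"
    extent: tuple = (61, 61)
    h: float = 1.0
    block: int = 20           # block side in voxels, doubly occupied
    D1: float = 1.0
    D2: float = 1.0
    D3: float = 1.0
    alpha_adh: float = 0.0
    trials: int = 100
    t_end: float = math.inf
    snapshot_times: tuple = ()
    seed: int = 0

    def __post_init__(self):
        _validate_common(self)
        if self.block < 1:
            raise ConfigurationError("block side must be >= 1")
        if self.alpha_adh < 0:
            raise ConfigurationError("alpha_adh must be >= 0")


@dataclass
class TrialResult:
    """Outcome of a multi-trial experiment on a fixed grid."""
    grid: Grid
    config: object
    trajectories: list
    average_density: np.ndarray
    metrics: dict
    per_trial: pd.DataFrame


def relaxation_experiment(config: RelaxationConfig) -> TrialResult:
    """Run ``trials`` independent relaxations of a doubly occupied block
    and average the final occupancy on the fixed grid.

    Every trial runs to absorption (no doubly occupied voxel remains), so
    the cell number is conserved and the averaged density measures only
    the shape of the relaxed colony.  Isotropy metrics compare it against
    the equal-area reference circle.
    """
    from .io_analysis import average_density, shape_metrics

    grid = build_structured_grid(
        config.grid_kind, config.extent, config.h,
        origin=_centered_origin(config.extent, config.h))
    L = assemble_laplacian(grid)
    occ0 = square_block(grid, config.block, value=2)
    constants = RateConstants(config.D1, config.D2, config.D3,
                              alpha_adh=config.alpha_adh)
    children = np.random.SeedSequence(config.seed).spawn(config.trials)
    trajectories = []
    rows = []
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        state = initialize_state(grid, occ0)
        traj = run_loop(Model(constants), state, grid, rng,
                        t_end=config.t_end, L=L,
                        snapshot_times=config.snapshot_times)
        trajectories.append(traj)
        final = np.maximum(traj.snapshots[-1].u, 0).astype(float)
        m = shape_metrics(final, grid)
        rows.append({"trial": k, "t_final": traj.snapshots[-1].t,
                     "n_events": traj.n_events,
                     "n_cells": int(final.sum()),
                     "anisotropy": m["anisotropy"],
                     "centroid_x": m["centroid"][0],
                     "centroid_y": m["centroid"][1]})
    avg = average_density([t.snapshots[-1].u for t in trajectories])
    metrics = shape_metrics(avg, grid)
    return TrialResult(grid=grid, config=config, trajectories=trajectories,
                       average_density=avg, metrics=metrics,
                       per_trial=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Slit chemo-repulsion

@dataclass
class SlitConfig:
    """Chemo-repulsion of a neuronal explant away from a Slit line source."""
    extent: tuple = (101, 101)
    h: float = 1.0
    radius: float = 10.0      # initial explant radius, doubly occupied
    chi1: float = 100.0       # drift sensitivity inside the pressure solve
    chi2: float = 5.0         # active down-gradient movement affinity
    D_S: float = 50.0         # Slit diffusivity
    k: float = 0.1            # Slit degradation rate
    Q: float = 2.0            # line source strength
    X_s: float = 50.0         # source line position
    D1: float = 1.0
    D2: float = 1.0
    D3: float = 1.0
    trials: int = 100
    t_end: float = 1000.0
    snapshot_times: tuple = ()
    seed: int = 0

    def __post_init__(self):
        _validate_common(self)
        if self.radius <= 0:
            raise ConfigurationError("explant radius must be positive")
        if min(self.D_S, self.k, self.Q) <= 0:
            raise ConfigurationError("D_S, k and Q must be positive")


class SlitModel(Model):
    """Pressure mechanics with chemotactic drift and active repulsion."""

    def __init__(self, constants: RateConstants, S: np.ndarray,
                 L: LaplacianOperator):
        super().__init__(constants)
        self.S = S
        self.L = L

    def fields(self, state, grid, solver):
        p = compute_pressure_with_drift(state, grid, self.L, self.S,
                                        self.constants.chi1)
        return {"pressure": p, "slit": self.S}

    def extra_edge_current(self, state, grid, fields):
        return drift_edge_currents(fields["pressure"], self.S, grid,
                                   self.constants.chi1, self.constants.chi2)


def slit_experiment(config: SlitConfig) -> TrialResult:
    """Relax a doubly occupied circular explant in a Slit gradient.

    The explant starts at the domain centre (origin); the Slit source is
    the line ``x1 = X_s``.  Reported metrics include per-trial centroid
    displacement along ``x1`` relative to the initial centre — negative
    values mean net movement away from the source.
    """
    from .io_analysis import average_density, shape_metrics

    grid = build_structured_grid(
        "cartesian2d", config.extent, config.h,
        origin=_centered_origin(config.extent, config.h))
    L = assemble_laplacian(grid)
    S = slit_field(grid, config.D_S, config.k, config.Q, config.X_s)
    occ0 = circular_region(grid, config.radius, value=2)
    x0 = float(np.average(grid.centers[:, 0], weights=np.maximum(occ0, 0)))
    constants = RateConstants(config.D1, config.D2, config.D3,
                              chi1=config.chi1, chi2=config.chi2)
    children = np.random.SeedSequence(config.seed).spawn(config.trials)
    trajectories, rows = [], []
    for k, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        state = initialize_state(grid, occ0)
        traj = run_loop(SlitModel(constants, S, L), state, grid, rng,
                        t_end=config.t_end, L=L,
                        snapshot_times=config.snapshot_times)
        trajectories.append(traj)
        final = np.maximum(traj.snapshots[-1].u, 0).astype(float)
        cx = float(np.average(grid.centers[:, 0], weights=final))
        rows.append({"trial": k, "n_events": traj.n_events,
                     "n_cells": int(final.sum()),
                     "centroid_x": cx, "displacement_x": cx - x0})
    avg = average_density([t.snapshots[-1].u for t in trajectories])
    metrics = shape_metrics(avg, grid)
    metrics["initial_centroid_x"] = x0
    metrics["centroid_displacement_x"] = metrics["centroid"][0] - x0
    return TrialResult(grid=grid, config=config, trajectories=trajectories,
                       average_density=avg, metrics=metrics,
                       per_trial=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Delta-Notch lateral inhibition on a growing tissue

@dataclass(frozen=True)
class DeltaNotchParams:
    """Dimensionless lateral-inhibition model parameters.

    ``n' = speed_factor * (f(dbar) - n)``,
    ``d' = speed_factor * v * (g(n) - d)`` with Hill functions
    ``f(x) = x^k / (a + x^k)`` (Notch activation by neighbour Delta) and
    ``g(x) = 1 / (1 + b x^h)`` (Delta inhibition by own Notch).
    ``speed_factor`` rescales the whole right-hand side (1 = signalling on
    a par with growth; 50 = quasi-steady signalling).
    """
    a: float = 0.01
    b: float = 100.0
    v: float = 1.0
    k: float = 2.0
    h: float = 2.0
    speed_factor: float = 1.0

    def __post_init__(self):
        if min(self.a, self.b, self.v, self.k, self.h,
               self.speed_factor) <= 0:
            raise ConfigurationError("Delta-Notch parameters must be positive")

    def f(self, x):
        xk = np.clip(x, 0.0, None) ** self.k
        return xk / (self.a + xk)

    def g(self, x):
        return 1.0 / (1.0 + self.b * np.clip(x, 0.0, None) ** self.h)


def delta_notch_rhs(cells, state: PopulationState, grid: Grid,
                    params: DeltaNotchParams) -> np.ndarray:
    """Right-hand side of the coupled Delta-Notch system.

    ``cells`` is a list of living cells (with ``internal_state = (n, d)``)
    in the order the derivative rows are returned.  The trans-activation
    input ``dbar`` of a cell is the arithmetic mean of Delta over its
    neighbouring cells: every cell in an edge-adjacent voxel plus, for a
    doubly occupied voxel, the co-occupant cell; a cell with no neighbours
    sees ``dbar = 0``.  Raises on negative internal states.
    """
    states = np.array([c.internal_state for c in cells])
    if states.size and states.min() < 0:
        raise ValueError("negative Notch/Delta state")
    A = _averaging_matrix(cells, state, grid)
    return _dn_derivative(states, A, params)


def _averaging_matrix(cells, state, grid) -> sp.csr_matrix:
    index_of = {c.id: k for k, c in enumerate(cells)}
    rows, cols, vals = [], [], []
    for k, c in enumerate(cells):
        nbr_ids = [cid for cid in state.living_in(c.voxel) if cid != c.id]
        for jvox in grid.neighbours(c.voxel):
            nbr_ids.extend(state.living_in(int(jvox)))
        if nbr_ids:
            wgt = 1.0 / len(nbr_ids)
            for cid in nbr_ids:
                rows.append(k)
                cols.append(index_of[cid])
                vals.append(wgt)
    n = len(cells)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _dn_derivative(states, A, params):
    n, d = states[:, 0], states[:, 1]
    dbar = A @ d
    out = np.empty_like(states)
    out[:, 0] = params.speed_factor * (params.f(dbar) - n)
    out[:, 1] = params.speed_factor * params.v * (params.g(n) - d)
    return out


def make_delta_notch_rhs(state: PopulationState, grid: Grid,
                         params: DeltaNotchParams):
    """Stacked-vector rhs ``f(t, y)`` for the engine's ODE integrator,
    frozen against the *current* contact topology (rebuild after any
    event that moves, adds or removes cells)."""
    cells = [c for c in state.cells.values()
             if c.alive and c.internal_state is not None]
    A = _averaging_matrix(cells, state, grid)

    def rhs(t, y):
        states = y.reshape(-1, 2)
        return _dn_derivative(states, A, params).ravel()

    return rhs


@dataclass
class NotchConfig:
    """Delta-Notch patterning on a tissue grown by central proliferation."""
    extent: tuple = (40, 40)       # hexagonal lattice
    h: float = 1.0
    region_radius: float = 3.0     # proliferative region (fixed, initial)
    prolif_rate: float = 1.0       # per eligible cell
    target_cells: int = 1000
    D1: float = 1.0
    D2: float = 1.0
    D3: float = 1.0
    params: DeltaNotchParams = field(default_factory=DeltaNotchParams)
    notch_threshold: float = 0.5
    t_end: float = math.inf
    snapshot_times: tuple = (5.0, 40.0, 70.0, 100.0)
    seed: int = 0
    track_rhs_norm: bool = False

    def __post_init__(self):
        _validate_common(self)
        if self.target_cells < 1:
            raise ConfigurationError("target_cells must be >= 1")
        if self.prolif_rate < 0:
            raise ConfigurationError("prolif_rate must be >= 0")


class NotchModel(Model):
    """Mechanics plus central proliferation plus per-cell Delta-Notch ODEs.

    Cells whose *current* voxel centre lies inside the fixed initial
    circular region proliferate at a constant rate (only singly occupied
    voxels have room); daughters inherit the mother's (n, d) state.
    """

    def __init__(self, constants, params: DeltaNotchParams,
                 region_mask: np.ndarray, prolif_rate: float,
                 target_cells: int, track_rhs_norm: bool = False):
        super().__init__(constants)
        self.params = params
        self.region_mask = region_mask
        self.prolif_rate = prolif_rate
        self.target_cells = target_cells
        self._rhs = None
        self.rhs_norms: list = []
        self.track_rhs_norm = track_rhs_norm

    def extra_events(self, state, grid, fields):
        events, rates = [], []
        for i in np.flatnonzero(self.region_mask):
            if state.u[i] == 1:
                events.append(Event("proliferate", int(i)))
                rates.append(self.prolif_rate)
        return EventSet(events, rates)

    def ode_rhs(self, state, grid):
        if self._rhs is None:
            self._rhs = make_delta_notch_rhs(state, grid, self.params)
        return self._rhs

    def notify(self, state, event):
        self._rhs = None  # contact topology changed
        if self.track_rhs_norm:
            cells = [c for c in state.cells.values()
                     if c.alive and c.internal_state is not None]
            if cells:
                der = delta_notch_rhs(cells, state, grid=self._grid,
                                      params=self.params)
                # distance from signalling equilibrium, independent of the
                # overall time-scale factor
                der = der / self.params.speed_factor
                self.rhs_norms.append(
                    (state.t, float(np.median(np.linalg.norm(der, axis=1)))))

    def finished(self, state):
        return state.n_living >= self.target_cells


def delta_notch_experiment(config: NotchConfig):
    """Grow a tissue by central proliferation while integrating the
    Delta-Notch ODEs between events; halt at the target cell count.

    Initial cells singly occupy the voxels of the central circular region
    with (n, d) drawn uniformly from (0, 1).  Returns the trajectory and a
    per-snapshot pattern summary (cell count and high-Notch fraction with
    threshold ``n > notch_threshold``).
    """
    grid = build_structured_grid(
        "hexagonal", config.extent, config.h,
        origin=(0.0, 0.0))
    L = assemble_laplacian(grid)
    center = grid.centers.mean(axis=0)
    region = np.linalg.norm(grid.centers - center, axis=1) \
        <= config.region_radius + 1e-9
    occ0 = np.where(region, 1, 0)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    state = initialize_state(grid, occ0,
                             internal_state_init=lambda k: rng.uniform(0, 1, 2))
    constants = RateConstants(config.D1, config.D2, config.D3)
    model = NotchModel(constants, config.params, region,
                       config.prolif_rate, config.target_cells,
                       track_rhs_norm=config.track_rhs_norm)
    model._grid = grid
    traj = run_loop(model, state, grid, rng, t_end=config.t_end, L=L,
                    snapshot_times=config.snapshot_times)
    rows = []
    for snap in traj.snapshots:
        if snap.internal:
            notch = np.array([v[0] for v in snap.internal.values()])
            frac = float(np.mean(notch > config.notch_threshold))
        else:
            frac = math.nan
        rows.append({"t": snap.t, "n_cells": int(np.maximum(snap.u, 0).sum()),
                     "high_notch_fraction": frac})
    return traj, pd.DataFrame(rows), model


# ---------------------------------------------------------------------------
# avascular tumour

@dataclass(frozen=True)
class TumourParams:
    """Oxygen-driven tumour kinetics (rates per second, thresholds on the
    oxygen scale normalized to 1 at the outer boundary)."""
    lam: float = 0.0015        # oxygen consumption per living cell
    kappa_prol: float = 0.65   # oxygen threshold for proliferation
    rho_prol: float = 0.125    # proliferation rate
    kappa_death: float = 0.55  # oxygen threshold for survival
    rho_death: float = 0.125   # death rate
    rho_deg: float = 0.01      # degradation rate of dead cells

    def __post_init__(self):
        if min(self.lam, self.kappa_prol, self.rho_prol, self.kappa_death,
               self.rho_death, self.rho_deg) < 0:
            raise ConfigurationError("tumour parameters must be >= 0")


class OxygenSolver:
    """Direct solver for the oxygen diffusion problem on the fixed grid.

    ``-L c = -lam * a(u)`` with ``c = 1`` on the external boundary; the
    system matrix never changes, so it is factorized once.
    """

    def __init__(self, grid: Grid, L: LaplacianOperator, lam: float):
        self.grid = grid
        self.lam = lam
        bdry = grid.external_boundary
        if not bdry.any():
            raise ConfigurationError(
                "oxygen problem needs a flagged external boundary")
        self.interior = np.flatnonzero(~bdry)
        self.bdry = np.flatnonzero(bdry)
        M = (-L.matrix).tocsr()
        self._A = spla.splu(M[self.interior][:, self.interior].tocsc())
        # boundary coupling at c = 1 on the external boundary
        self._b_coupling = -np.asarray(
            M[self.interior][:, self.bdry].sum(axis=1)).ravel()

    def solve(self, state: PopulationState) -> np.ndarray:
        a = np.maximum(state.u, 0).astype(float)  # living cells per voxel
        c = np.ones(self.grid.n_voxels)
        rhs = -self.lam * a[self.interior] + self._b_coupling
        c[self.interior] = self._A.solve(rhs)
        return c


def tumour_oxygen(state: PopulationState, grid: Grid, L: LaplacianOperator,
                  lam: float) -> np.ndarray:
    """Oxygen concentration for the current population: living cells
    consume at rate ``lam`` each (doubly occupied voxels twice as much;
    dead cells none), oxygen enters at the fixed outer boundary where
    ``c = 1``.  One-shot convenience wrapper over :class:`OxygenSolver`."""
    return OxygenSolver(grid, L, lam).solve(state)


def tumour_events(state: PopulationState, c: np.ndarray,
                  params: TumourParams) -> EventSet:
    """Oxygen-gated kinetic events.

    Singly occupied voxels proliferate at ``rho_prol`` where
    ``c > kappa_prol`` and die at ``rho_death`` where ``c < kappa_death``
    (strict inequalities: a concentration exactly at a threshold generates
    no event); voxels holding a dead cell degrade at ``rho_deg``
    regardless of oxygen.  Death is defined only for ``u_i = 1`` — a cell
    in a doubly occupied hypoxic voxel must first lose its neighbour by
    movement before it can die.
    """
    events, rates = [], []
    for i in np.flatnonzero(state.u == 1):
        i = int(i)
        if c[i] > params.kappa_prol:
            events.append(Event("proliferate", i))
            rates.append(params.rho_prol)
        if c[i] < params.kappa_death:
            events.append(Event("die", i))
            rates.append(params.rho_death)
    for i in np.flatnonzero(state.u == -1):
        events.append(Event("degrade", int(i)))
        rates.append(params.rho_deg)
    return EventSet(events, rates)


@dataclass
class TumourConfig:
    """Avascular tumour growth from a 5x5 seed of singly occupied voxels.

    The domain is sized so that the steady-state oxygen depression under
    a colony reachable within the horizon crosses both the proliferation
    and the survival thresholds (the boundary supplies oxygen at c = 1,
    so too small a domain can never go hypoxic)."""
    extent: tuple = (81, 81)
    h: float = 1.0
    block: int = 5
    D1: float = 0.01
    D2: float = 25.0
    D3: float = 0.01
    params: TumourParams = field(default_factory=TumourParams)
    t_end: float = 500.0
    snapshot_times: tuple = ()
    seed: int = 0

    def __post_init__(self):
        _validate_common(self)
        if self.block < 1:
            raise ConfigurationError("block side must be >= 1")


class TumourModel(Model):
    def __init__(self, constants, params: TumourParams,
                 oxygen_solver: OxygenSolver):
        super().__init__(constants)
        self.params = params
        self.oxygen_solver = oxygen_solver

    def fields(self, state, grid, solver):
        return {"pressure": solver.solve(state),
                "oxygen": self.oxygen_solver.solve(state)}

    def extra_events(self, state, grid, fields):
        return tumour_events(state, fields["oxygen"], self.params)


def tumour_experiment(config: TumourConfig):
    """Run one realization of the avascular tumour model.

    Returns the trajectory and a per-snapshot table of cell counts by
    type: ``proliferative`` (living, ``c > kappa_prol``), ``quiescent``
    (living, ``c <= kappa_prol``) and ``necrotic`` (voxels at ``u = -1``).
    """
    grid = build_structured_grid(
        "cartesian2d", config.extent, config.h,
        origin=_centered_origin(config.extent, config.h))
    L = assemble_laplacian(grid)
    occ0 = square_block(grid, config.block, value=1)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    state = initialize_state(grid, occ0)
    constants = RateConstants(config.D1, config.D2, config.D3)
    model = TumourModel(constants, config.params,
                        OxygenSolver(grid, L, config.params.lam))
    traj = run_loop(model, state, grid, rng, t_end=config.t_end, L=L,
                    snapshot_times=config.snapshot_times)
    rows = []
    for snap in traj.snapshots:
        c = snap.fields["oxygen"]
        living = np.maximum(snap.u, 0)
        prol = int(living[c > config.params.kappa_prol].sum())
        rows.append({
            "t": snap.t,
            "n_living": int(living.sum()),
            "proliferative": prol,
            "quiescent": int(living.sum()) - prol,
            "necrotic": int(np.sum(snap.u == -1)),
        })
    return traj, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dispatch

def run(config):
    """Dispatch a configuration dataclass to its experiment pipeline."""
    if isinstance(config, RelaxationConfig):
        return relaxation_experiment(config)
    if isinstance(config, SlitConfig):
        return slit_experiment(config)
    if isinstance(config, NotchConfig):
        return delta_notch_experiment(config)
    if isinstance(config, TumourConfig):
        return tumour_experiment(config)
    raise ConfigurationError(f"unknown experiment config {type(config)!r}")
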