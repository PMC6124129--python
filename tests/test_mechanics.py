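"""Pressure solves, edge currents, movement rates, adhesion and drift."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dlcm import (NoFreeBoundaryError, RateConstants, assemble_laplacian,
                  build_structured_grid, compute_pressure,
                  compute_pressure_with_drift, edge_current,
                  enumerate_move_events, initialize_state, slit_field)
from dlcm.mechanics import (EventSet, active_drift_current,
                            adhesion_correction)
from dlcm.population_state import Event, active_domain

from conftest import random_occupancy

# hand-solved restricted system for the 1x3 strip u = (1, 2, 1):
# 4 p_A - p_B = 0;  4 p_B - p_A - p_C = 1;  4 p_C - p_B = 0
P_A, P_B = 1.0 / 14.0, 2.0 / 7.0


class TestPressure:
    def test_no_source_means_zero_pressure_and_no_events(self, grid5):
        occ = np.zeros(25, dtype=int)
        occ[[11, 12, 13]] = 1
        state = initialize_state(grid5, occ)
        L = assemble_laplacian(grid5)
        p = compute_pressure(state, grid5, L)
        assert not p.any()
        events = enumerate_move_events(state, grid5, p, RateConstants())
        assert len(events) == 0 and events.total == 0.0

    def test_strip_matches_hand_solution(self, grid5, strip_state, laplacian5):
        p = compute_pressure(strip_state, grid5, laplacian5)
        assert p[11] == pytest.approx(P_A, abs=1e-12)
        assert p[12] == pytest.approx(P_B, abs=1e-12)
        assert p[13] == pytest.approx(P_A, abs=1e-12)
        # zero on the free boundary and outside
        _, bdry = active_domain(strip_state, grid5)
        assert not p[bdry].any()

    def test_pressure_nonnegative_max_at_source(self, grid5, laplacian5):
        rng = np.random.default_rng(5)
        for _ in range(10):
            occ = random_occupancy(grid5, rng)
            state = initialize_state(grid5, occ)
            p = compute_pressure(state, grid5, laplacian5)
            assert p.min() >= -1e-13
            assert p.argmax() in np.flatnonzero(occ == 2)

    def test_symmetric_configuration_gives_symmetric_pressure(self):
        grid = build_structured_grid("cartesian2d", (7, 7), h=1.0)
        L = assemble_laplacian(grid)
        occ = np.zeros(49, dtype=int)
        center = 24
        occ[center] = 2
        for i in range(49):
            if i != center and np.linalg.norm(
                    grid.centers[i] - grid.centers[center]) <= 2.0:
                occ[i] = 1
        p = compute_pressure(initialize_state(grid, occ), grid, L)
        field = p.reshape(7, 7)
        np.testing.assert_allclose(field, np.rot90(field), atol=1e-12)
        np.testing.assert_allclose(field, field.T, atol=1e-12)

    def test_full_grid_with_source_raises(self):
        grid = build_structured_grid("cartesian2d", (3, 3), h=1.0)
        occ = np.ones(9, dtype=int)
        occ[4] = 2
        with pytest.raises(NoFreeBoundaryError):
            compute_pressure(initialize_state(grid, occ), grid,
                             assemble_laplacian(grid))

    @pytest.mark.parametrize("extent", [(6, 6), (10, 10), (9, 5)])
    def test_sparse_solve_matches_dense_oracle(self, extent):
        """Restricted sparse solve vs brute-force dense solve of the same
        equations on grids of at most 100 voxels."""
        grid = build_structured_grid("cartesian2d", extent, h=1.0)
        L = assemble_laplacian(grid)
        rng = np.random.default_rng(11)
        for _ in range(5):
            occ = random_occupancy(grid, rng)
            state = initialize_state(grid, occ)
            p = compute_pressure(state, grid, L)
            idx = np.flatnonzero(occ != 0)
            A = -L.matrix.toarray()[np.ix_(idx, idx)]
            ref = np.linalg.solve(A, (occ[idx] == 2).astype(float))
            denom = max(np.abs(ref).max(), 1e-300)
            assert np.abs(p[idx] - ref).max() / denom < 1e-12


class TestEdgeCurrent:
    def test_equal_pressure_gives_zero(self, grid5):
        p = np.ones(25)
        assert edge_current(p, grid5, 11, 12) == 0.0

    def test_strip_currents(self, grid5, strip_state, laplacian5):
        p = compute_pressure(strip_state, grid5, laplacian5)
        assert edge_current(p, grid5, 12, 11) == pytest.approx(3.0 / 14.0)
        assert edge_current(p, grid5, 11, 12) == pytest.approx(-3.0 / 14.0)
        assert edge_current(p, grid5, 11, 10) == pytest.approx(1.0 / 14.0)

    def test_non_neighbours_rejected(self, grid5):
        with pytest.raises(ValueError):
            edge_current(np.zeros(25), grid5, 0, 24)


class TestMoveRates:
    def test_strip_rate_table(self, grid5, strip_state, laplacian5):
        p = compute_pressure(strip_state, grid5, laplacian5)
        events = enumerate_move_events(strip_state, grid5, p, RateConstants())
        rates = {(e.i, e.j): r for e, r in events}
        A, B, C = 11, 12, 13
        assert rates[(B, A)] == pytest.approx(3 / 14)
        assert rates[(B, C)] == pytest.approx(3 / 14)
        for j in (7, 17):  # B's empty lateral neighbours
            assert rates[(B, j)] == pytest.approx(4 / 14)
        for j in (6, 16, 10):  # A's empty neighbours
            assert rates[(A, j)] == pytest.approx(1 / 14)
        assert len(rates) == 10
        assert events.total == pytest.approx(10 / 7)

    def test_boundary_source_balance(self, grid5, strip_state, laplacian5):
        """Divergence identity: with D2 = D3 the total rate into empty
        boundary voxels equals the enclosed sources, as does the total
        rate out of the single source voxel."""
        p = compute_pressure(strip_state, grid5, laplacian5)
        events = enumerate_move_events(strip_state, grid5, p, RateConstants())
        into_empty = sum(r for e, r in events if strip_state.u[e.j] == 0)
        out_of_source = sum(r for e, r in events if e.i == 12)
        assert into_empty == pytest.approx(1.0, abs=1e-10)
        assert out_of_source == pytest.approx(1.0, abs=1e-10)

    def test_all_singles_is_absorbing(self, grid5, laplacian5):
        occ = np.zeros(25, dtype=int)
        occ[[6, 7, 8]] = 1
        state = initialize_state(grid5, occ)
        p = compute_pressure(state, grid5, laplacian5)
        assert len(enumerate_move_events(state, grid5, p,
                                         RateConstants())) == 0

    def test_d1_vs_d2_classified_by_visited_flag(self, grid5, strip_state,
                                                 laplacian5):
        strip_state.visited[10] = True  # pretend A's left neighbour was visited
        p = compute_pressure(strip_state, grid5, laplacian5)
        constants = RateConstants(D1=1.0, D2=5.0, D3=1.0)
        rates = {(e.i, e.j): r
                 for e, r in enumerate_move_events(strip_state, grid5, p,
                                                   constants)}
        assert rates[(11, 10)] == pytest.approx(5.0 / 14.0)
        assert rates[(11, 6)] == pytest.approx(1.0 / 14.0)

    def test_dead_voxels_block_movement(self, grid5, laplacian5):
        occ = np.zeros(25, dtype=int)
        occ[[11, 12, 13]] = [1, 2, 1]
        state = initialize_state(grid5, occ)
        state.apply_event(Event("die", 11))  # u_A -> -1
        p = compute_pressure(state, grid5, laplacian5)
        events = enumerate_move_events(state, grid5, p, RateConstants())
        assert all(e.j != 11 for e, _ in events)
        assert all(e.i != 11 for e, _ in events)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_divergence_identity_on_random_configurations(seed):
    """Total current over the free boundary equals the number of unit
    sources, for arbitrary occupancy configurations."""
    grid = build_structured_grid("cartesian2d", (9, 9), h=1.0)
    L = assemble_laplacian(grid)
    occ = random_occupancy(grid, np.random.default_rng(seed))
    state = initialize_state(grid, occ)
    p = compute_pressure(state, grid, L)
    omega, bdry = active_domain(state, grid)
    bdry = set(bdry)
    total = sum(edge_current(p, grid, int(i), int(j))
                for i in omega for j in grid.neighbours(int(i))
                if int(j) in bdry)
    assert total == pytest.approx(float(np.sum(occ == 2)), abs=1e-10)


class TestAdhesion:
    def test_zero_constant_gives_zero(self, grid5, strip_state):
        assert adhesion_correction(strip_state, grid5, 12, 11, 0.0) == 0.0

    def test_diametrically_opposite_neighbour(self, grid5):
        # cell at 12 moving to 13 with a populated neighbour at 11:
        # r_ij . r_ik = -1, so delta I = -alpha * e_ik * d_ij
        occ = np.zeros(25, dtype=int)
        occ[[11, 12]] = [1, 2]
        state = initialize_state(grid5, occ)
        alpha = 0.7
        assert adhesion_correction(state, grid5, 12, 13, alpha) == \
            pytest.approx(-alpha)

    def test_orthogonal_neighbour_contributes_nothing(self, grid5):
        occ = np.zeros(25, dtype=int)
        occ[[7, 12]] = [1, 2]  # 7 is orthogonal to the move 12 -> 13
        state = initialize_state(grid5, occ)
        assert adhesion_correction(state, grid5, 12, 13, 1.0) == 0.0

    def test_strong_adhesion_floors_rates_at_zero(self, grid5, strip_state,
                                                  laplacian5):
        p = compute_pressure(strip_state, grid5, laplacian5)
        events = enumerate_move_events(
            strip_state, grid5, p, RateConstants(alpha_adh=100.0))
        assert all(r > 0 for _, r in events)
        # B's moves towards A and C are opposed by the cell on the other
        # side and are fully suppressed at this adhesion strength
        assert (12, 11) not in {(e.i, e.j) for e, _ in events}


class TestDrift:
    def test_chi1_zero_and_constant_S_reduce_to_plain_pressure(
            self, grid5, strip_state, laplacian5):
        p0 = compute_pressure(strip_state, grid5, laplacian5)
        S = np.linspace(0.0, 1.0, 25)
        p1 = compute_pressure_with_drift(strip_state, grid5, laplacian5,
                                         S, 0.0)
        p2 = compute_pressure_with_drift(strip_state, grid5, laplacian5,
                                         np.full(25, 3.7), 10.0)
        np.testing.assert_array_equal(p0, p1)
        np.testing.assert_allclose(p0, p2, atol=1e-14)

    def test_manufactured_1d_against_dense_assembly(self):
        """Linear S on a 1D strip: the sparse drift solve must match a
        dense solve of the identical discrete equations assembled by an
        independent loop."""
        grid = build_structured_grid("cartesian2d", (9, 1), h=1.0)
        L = assemble_laplacian(grid)
        occ = np.array([0, 1, 1, 2, 1, 2, 1, 1, 0])
        state = initialize_state(grid, occ)
        S = 0.3 * grid.centers[:, 0]
        chi1 = 0.8
        p = compute_pressure_with_drift(state, grid, L, S, chi1)

        idx = np.flatnonzero(occ != 0)
        pos = {int(v): k for k, v in enumerate(idx)}
        n = len(idx)
        A = np.zeros((n, n))
        b = (occ[idx] == 2).astype(float)
        for row, i in enumerate(idx):
            for j in grid.neighbours(int(i)):
                w = 1.0
                dS = chi1 * (S[i] - S[j])
                A[row, row] += w * (1 + dS / 2)
                if int(j) in pos:
                    A[row, pos[int(j)]] += w * (-1 + dS / 2)
        ref = np.linalg.solve(A, b)
        np.testing.assert_allclose(p[idx], ref, rtol=1e-12)


class TestSlitField:
    PARAMS = dict(D_S=50.0, k=0.1, Q=2.0)

    def test_peak_value_on_source_line(self):
        grid = build_structured_grid("cartesian2d", (11, 3), h=1.0)
        S = slit_field(grid, X_s=5.0, **self.PARAMS)
        peak = self.PARAMS["Q"] / (2 * np.sqrt(self.PARAMS["k"]
                                               * self.PARAMS["D_S"]))
        assert peak == pytest.approx(1 / np.sqrt(5))
        assert S.max() == pytest.approx(peak)
        np.testing.assert_allclose(S.reshape(3, 11)[:, 5], peak)

    def test_profile_symmetric_about_source(self):
        grid = build_structured_grid("cartesian2d", (11, 1), h=1.0)
        S = slit_field(grid, X_s=5.0, **self.PARAMS)
        np.testing.assert_allclose(S, S[::-1])
        assert np.all(np.diff(S[:6]) > 0)  # increases towards the source

    def test_active_current_points_away_from_source(self):
        grid = build_structured_grid("cartesian2d", (51, 1), h=1.0)
        S = slit_field(grid, X_s=50.0, **self.PARAMS)
        # voxels at x1 = 49, 50: moving 50 -> 49 is down-gradient
        assert active_drift_current(S, grid, 50, 49, chi2=5.0) > 0
        assert active_drift_current(S, grid, 49, 50, chi2=5.0) < 0
        assert active_drift_current(S, grid, 50, 49, chi2=0.0) == 0.0
        assert active_drift_current(np.ones(51), grid, 50, 49, 5.0) == 0.0


class TestEventSet:
    def test_zero_rate_events_not_stored(self):
        es = EventSet([Event("move", 0, 1), Event("move", 1, 0)], [0.0, 2.0])
        assert len(es) == 1 and es.total == 2.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            EventSet([Event("move", 0, 1)], [-1.0])
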