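"""Unit and property tests for the lattice, agents, and event rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stemca import (
    Action,
    CellKind,
    Event,
    Lattice,
    SimulationParameters,
    VON_NEUMANN,
    draw_action,
    execute_migration,
    execute_proliferation,
    step,
    vacant_neighbors,
)


# ---------------------------------------------------------------------------
# SimulationParameters
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "bad",
    [
        dict(rho_max=-1),
        dict(p_s=1.5),
        dict(mu=-2),
        dict(lattice_size=2),
        dict(max_cells=0),
        dict(lattice_size=10, max_cells=101),
        dict(neighborhood="hex"),
        dict(mu=30),  # 1/24 + 30/24 > 1: invalid event partition
    ],
)
def test_invalid_parameters_rejected(bad):
    with pytest.raises(ValueError):
        SimulationParameters(**bad)


def test_event_probabilities_follow_rates():
    p = SimulationParameters(mu=15)
    assert p.p_proliferate == pytest.approx(1 / 24)
    assert p.p_migrate == pytest.approx(15 / 24)
    assert SimulationParameters(mu=0).p_migrate == 0.0


# ---------------------------------------------------------------------------
# vacant_neighbors
# ---------------------------------------------------------------------------


def test_vacant_neighbors_counts():
    lat = Lattice(10)
    lat.add_cell(CellKind.CSC, (5, 5))
    assert len(vacant_neighbors(lat, (5, 5))) == 8
    lat2 = Lattice(10)
    lat2.add_cell(CellKind.CSC, (0, 0))
    assert len(vacant_neighbors(lat2, (0, 0))) == 3
    # fully surrounded cell
    lat3 = Lattice(10)
    for r in range(4, 7):
        for c in range(4, 7):
            lat3.add_cell(CellKind.CC, (r, c), rho=1)
    assert vacant_neighbors(lat3, (5, 5)) == []
    assert len(vacant_neighbors(lat3, (5, 5), VON_NEUMANN)) == 0


def test_vacant_neighbors_out_of_bounds():
    lat = Lattice(5)
    with pytest.raises(IndexError):
        vacant_neighbors(lat, (5, 0))


@given(
    occupied=st.sets(
        st.tuples(st.integers(0, 4), st.integers(0, 4)), max_size=25
    ),
    pos=st.tuples(st.integers(0, 4), st.integers(0, 4)),
)
def test_vacant_neighbors_matches_brute_force(occupied, pos):
    """The kernel agrees with a direct set-comprehension oracle."""
    lat = Lattice(5)
    for (r, c) in occupied:
        lat.add_cell(CellKind.CC, (r, c), rho=0)
    expected = {
        (pos[0] + dr, pos[1] + dc)
        for dr in (-1, 0, 1)
        for dc in (-1, 0, 1)
        if (dr, dc) != (0, 0)
        and 0 <= pos[0] + dr < 5
        and 0 <= pos[1] + dc < 5
        and (pos[0] + dr, pos[1] + dc) not in occupied
    }
    assert set(vacant_neighbors(lat, pos)) == expected


# ---------------------------------------------------------------------------
# draw_action
# ---------------------------------------------------------------------------


def test_no_space_always_quiesces(rng):
    p = SimulationParameters(mu=15)
    assert all(
        draw_action(p, False, rng) == Action.QUIESCE for _ in range(200)
    )


def test_zero_migration_never_migrates(rng):
    p = SimulationParameters(mu=0)
    draws = [draw_action(p, True, rng) for _ in range(2000)]
    assert Action.MIGRATE not in draws
    assert Action.PROLIFERATE in draws


def test_action_frequencies_match_partition(rng):
    """P(proliferate) = 1/24 and P(migrate) = mu/24 within 3 binomial SE."""
    p = SimulationParameters(mu=15)
    n = 20_000
    draws = np.array([int(draw_action(p, True, rng)) for _ in range(n)])
    for action, prob in [(0, 1 / 24), (1, 15 / 24)]:
        freq = np.mean(draws == action)
        se = np.sqrt(prob * (1 - prob) / n)
        assert abs(freq - prob) < 3 * se


# ---------------------------------------------------------------------------
# execute_proliferation / execute_migration
# ---------------------------------------------------------------------------


def _lone_cell(kind, rho=0, size=9):
    lat = Lattice(size)
    lat.add_cell(kind, (size // 2, size // 2), rho=rho)
    return lat, lat.cell_at((size // 2, size // 2))


def test_symmetric_csc_division(rng):
    lat, cell = _lone_cell(CellKind.CSC)
    p = SimulationParameters(p_s=1.0, rho_max=4)
    assert execute_proliferation(lat, cell, p, rng) == Event.DIVIDED_SYMMETRIC
    kinds = [c.kind for c in lat.cells()]
    assert kinds == [CellKind.CSC, CellKind.CSC]
    a, b = lat.cells()
    assert max(abs(a.position[0] - b.position[0]),
               abs(a.position[1] - b.position[1])) == 1
    assert lat.n_csc == 2


@pytest.mark.parametrize("rho_max", [1, 4])
def test_asymmetric_csc_division_daughter_capacity(rng, rho_max):
    lat, cell = _lone_cell(CellKind.CSC)
    p = SimulationParameters(p_s=0.0, rho_max=rho_max)
    assert execute_proliferation(lat, cell, p, rng) == Event.DIVIDED_ASYMMETRIC
    daughter = [c for c in lat.cells() if c.kind == CellKind.CC]
    assert len(daughter) == 1 and daughter[0].rho == rho_max
    assert lat.n_csc == 1  # parent preserved


def test_cc_division_decrements_both(rng):
    lat, cell = _lone_cell(CellKind.CC, rho=3)
    p = SimulationParameters(rho_max=3)
    assert execute_proliferation(lat, cell, p, rng) == Event.DIVIDED_CC
    rhos = sorted(c.rho for c in lat.cells())
    assert rhos == [2, 2]


def test_exhausted_cc_dies_on_division_decision(rng):
    lat, cell = _lone_cell(CellKind.CC, rho=0)
    p = SimulationParameters(rho_max=3)
    assert execute_proliferation(lat, cell, p, rng) == Event.DIED
    assert lat.occupancy_count == 0
    assert lat.cell_at(cell.position) is None


def test_proliferation_requires_space(rng):
    lat = Lattice(9)
    for r in range(3, 6):
        for c in range(3, 6):
            lat.add_cell(CellKind.CC, (r, c), rho=1)
    center = lat.cell_at((4, 4))
    with pytest.raises(RuntimeError):
        execute_proliferation(lat, center, SimulationParameters(), rng)
    with pytest.raises(RuntimeError):
        execute_migration(lat, center, rng)


def test_migration_conserves_population(rng):
    lat, cell = _lone_cell(CellKind.CC, rho=2)
    before = cell.position
    assert execute_migration(lat, cell, rng) == Event.MIGRATED
    assert lat.occupancy_count == 1
    (moved,) = lat.cells()
    assert moved.position != before
    assert lat.cell_at(before) is None
    assert max(abs(moved.position[0] - before[0]),
               abs(moved.position[1] - before[1])) == 1


# ---------------------------------------------------------------------------
# step
# ---------------------------------------------------------------------------


def test_step_empty_lattice_is_noop(rng, small_params):
    lat = Lattice(20)
    s = step(lat, small_params(lattice_size=20, max_cells=400), rng)
    assert (s.divisions, s.deaths, s.migrations, s.quiescent) == (0, 0, 0, 0)
    assert lat.occupancy_count == 0


def test_step_conservation_and_monotone_csc(small_params):
    """Per-step bookkeeping: dN = divisions - deaths, CSC never decreases,
    CC capacities stay within [0, rho_max], grid stays consistent."""
    params = small_params(rho_max=2, p_s=0.1, mu=5, max_cells=3000,
                          lattice_size=80)
    rng = np.random.default_rng(7)
    lat = Lattice(80)
    lat.add_cell(CellKind.CSC, (40, 40))
    prev_csc = 1
    for i in range(600):
        before = lat.occupancy_count
        s = step(lat, params, rng)
        assert lat.occupancy_count == before + s.divisions - s.deaths
        assert lat.n_csc >= prev_csc
        prev_csc = lat.n_csc
        n = lat.n_cells
        cc = lat.kinds[:n] == 0
        if cc.any():
            assert lat.rhos[:n][cc].min() >= 0
            assert lat.rhos[:n][cc].max() <= params.rho_max
    lat.check_consistency()
    assert lat.occupancy_count > 1  # the tumor actually grew


def test_single_immortal_csc_plateau():
    """p_s=0, mu=0, rho_max=0: the CSC persists alone with a bounded CC halo
    (daughters die on their first division attempt and never spread)."""
    params = SimulationParameters(rho_max=0, p_s=0.0, mu=0, lattice_size=30,
                                  max_cells=900, max_time_h=1e9)
    rng = np.random.default_rng(3)
    lat = Lattice(30)
    lat.add_cell(CellKind.CSC, (15, 15))
    from stemca import run_steps

    for _ in range(10):
        run_steps(lat, params, rng, 5000)
        assert lat.n_csc == 1
        assert 1 <= lat.occupancy_count <= 9  # CSC + Moore ring at most


def test_seed_determinism_step_level(small_params):
    params = small_params()
    results = []
    for _ in range(2):
        rng = np.random.default_rng(123)
        lat = Lattice(60)
        lat.add_cell(CellKind.CSC, (30, 30))
        summaries = [step(lat, params, rng) for _ in range(300)]
        results.append(
            (lat.n_cells, lat.n_csc, lat.grid.copy(),
             [(s.divisions, s.deaths, s.migrations) for s in summaries])
        )
    assert results[0][0] == results[1][0]
    assert results[0][1] == results[1][1]
    assert np.array_equal(results[0][2], results[1][2])
    assert results[0][3] == results[1][3]


def test_add_cell_rejects_occupied_site():
    lat = Lattice(5)
    lat.add_cell(CellKind.CSC, (2, 2))
    with pytest.raises(ValueError):
        lat.add_cell(CellKind.CC, (2, 2), rho=1)
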