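"""Agents, lattice, and per-step stochastic rules of the tumor automaton.

The model describes a solid tumor as agents on a 2-D square lattice.  Two
compartments exist:

* **CSC** (cancer stem cell): immortal, unlimited replicative potential.  On
  a division event it divides symmetrically with probability ``p_s`` (two
  CSCs) or asymmetrically (parent CSC plus a non-stem daughter endowed with
  proliferative capacity ``rho_max``).
* **CC** (non-stem cancer cell): mortal, carries a remaining proliferative
  capacity ``rho``.  A division decrements both parent and daughter to
  ``rho - 1``; a CC at ``rho = 0`` dies on its next division decision and
  frees its lattice site.

Each cell occupies exactly one lattice site.  In every one-hour time step a
cell with at least one vacant adjacent site draws a single action from a
partitioned uniform variate: proliferate with probability
``dt_h / cell_cycle_h``, migrate (one site hop) with probability
``mu * dt_h / 24``, otherwise remain quiescent.  Cells with no vacant
neighbor are quiescent unconditionally — spatial inhibition is the central
mechanism of the model.

The event rules are compiled with numba; the public per-operation wrappers
(:func:`vacant_neighbors`, :func:`draw_action`,
:func:`execute_proliferation`, :func:`execute_migration`, :func:`step`)
call the same compiled kernels that the bulk simulation loop uses.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterator, Optional, Tuple

import numpy as np
from numba import njit

__all__ = [
    "CellKind",
    "Action",
    "Event",
    "StepSummary",
    "SimulationParameters",
    "Cell",
    "Lattice",
    "MOORE",
    "VON_NEUMANN",
    "NEIGHBORHOODS",
    "vacant_neighbors",
    "draw_action",
    "execute_proliferation",
    "execute_migration",
    "step",
    "run_steps",
]

logger = logging.getLogger("stemca")

Coordinate = Tuple[int, int]


class CellKind(enum.IntEnum):
    """Agent compartment: mortal non-stem cell (CC) or cancer stem cell (CSC)."""

    CC = 0
    CSC = 1


class Action(enum.IntEnum):
    """Outcome of the per-step action draw."""

    PROLIFERATE = 0
    MIGRATE = 1
    QUIESCE = 2


class Event(enum.IntEnum):
    """What actually happened when a cell was processed."""

    DIVIDED_SYMMETRIC = 0   # CSC -> two CSCs
    DIVIDED_ASYMMETRIC = 1  # CSC -> CSC + CC(rho_max)
    DIVIDED_CC = 2          # CC(rho>=1) -> two CC(rho-1)
    DIED = 3                # CC(rho=0) drew PROLIFERATE
    MIGRATED = 4
    QUIESCENT = 5


# Neighborhood stencils (row, col offsets).  Moore (8 sites) is the default:
# it makes one site-hop per migration event correspond naturally to one cell
# width of displacement and is the common choice in this model family.
MOORE = np.array(
    [[-1, -1], [-1, 0], [-1, 1], [0, -1], [0, 1], [1, -1], [1, 0], [1, 1]],
    dtype=np.int64,
)
VON_NEUMANN = np.array([[-1, 0], [0, -1], [0, 1], [1, 0]], dtype=np.int64)

NEIGHBORHOODS = {"moore": MOORE, "vonneumann": VON_NEUMANN}


@dataclass(frozen=True)
class SimulationParameters:
    """Full parameter vector of one automaton configuration.

    Parameters
    ----------
    rho_max
        Maximum proliferative capacity conferred to a first-generation CC by
        asymmetric CSC division (generational life span), 0-10 in the
        reference sweep.
    p_s
        Probability of symmetric CSC division per division event (0.01 or
        0.10 in the reference sweep).
    mu
        Migration speed in cell widths (lattice sites) per day; one site hop
        per migration event, hence per-step hop probability ``mu * dt_h / 24``.
    cell_cycle_h
        Cell cycle time in hours (24 by default), i.e. one division attempt
        per day on average for an unconstrained cell.
    dt_h
        Time step in hours (1 by default).
    lattice_size
        Side length of the square lattice in sites (350 by default).
    site_width_um
        Physical site width in micrometres (metadata only; 10 by default so
        a site is one (10 um)^2 cell footprint).
    max_cells
        Stop once the total population reaches this size (50,000).
    max_time_h
        Stop once this much simulated time has elapsed (5 years = 43,800 h).
    record_interval_h
        Sampling interval for time series (7 days = 168 h).
    neighborhood
        ``"moore"`` (8 adjacent sites, default) or ``"vonneumann"`` (4).
    """

    rho_max: int = 5
    p_s: float = 0.01
    mu: float = 5
    cell_cycle_h: float = 24.0
    dt_h: float = 1.0
    lattice_size: int = 350
    site_width_um: float = 10.0
    max_cells: int = 50_000
    max_time_h: float = 43_800.0
    record_interval_h: float = 168.0
    neighborhood: str = "moore"

    def __post_init__(self) -> None:
        if self.rho_max < 0:
            raise ValueError("rho_max must be non-negative")
        if not 0.0 <= self.p_s <= 1.0:
            raise ValueError("p_s must lie in [0, 1]")
        if self.mu < 0:
            raise ValueError("mu (migration speed) must be non-negative")
        if self.cell_cycle_h <= 0 or self.dt_h <= 0:
            raise ValueError("cell_cycle_h and dt_h must be positive")
        if self.lattice_size < 3:
            raise ValueError("lattice_size must be at least 3")
        if self.max_cells < 1 or self.max_cells > self.lattice_size**2:
            raise ValueError("max_cells must lie in [1, lattice_size^2]")
        if self.max_time_h <= 0 or self.record_interval_h <= 0:
            raise ValueError("max_time_h and record_interval_h must be positive")
        if self.neighborhood not in NEIGHBORHOODS:
            raise ValueError(
                f"neighborhood must be one of {sorted(NEIGHBORHOODS)}"
            )
        if self.p_proliferate + self.p_migrate > 1.0 + 1e-12:
            raise ValueError(
                "invalid event-probability partition: "
                "dt_h/cell_cycle_h + mu*dt_h/24 must be <= 1 "
                f"(got {self.p_proliferate + self.p_migrate:.4f})"
            )

    @property
    def p_proliferate(self) -> float:
        """Per-step probability of a proliferation decision."""
        return self.dt_h / self.cell_cycle_h

    @property
    def p_migrate(self) -> float:
        """Per-step probability of a one-site migration hop."""
        return self.mu * self.dt_h / 24.0

    @property
    def offsets(self) -> np.ndarray:
        return NEIGHBORHOODS[self.neighborhood]


@dataclass(frozen=True)
class Cell:
    """Read-only view of one agent on the lattice."""

    kind: CellKind
    rho: int
    position: Coordinate
    index: int = field(default=-1, compare=False)


@dataclass
class StepSummary:
    """Event tallies for one (or several aggregated) time step(s)."""

    divisions: int = 0
    symmetric_divisions: int = 0
    deaths: int = 0
    migrations: int = 0
    quiescent: int = 0
    steps: int = 0
    edge_contact: bool = False


class Lattice:
    """Fixed-size 2-D occupancy grid; each site holds at most one cell.

    Cell state lives in flat numpy arrays (``rows``, ``cols``, ``kinds``,
    ``rhos``) indexed 0..``n_cells``-1; ``grid[r, c]`` holds the cell index
    occupying site ``(r, c)`` or -1 when vacant.  This layout is what the
    compiled step kernels operate on directly.
    """

    def __init__(self, size: int, capacity: Optional[int] = None) -> None:
        if size < 3:
            raise ValueError("lattice size must be at least 3")
        self.size = int(size)
        cap = int(capacity) if capacity is not None else self.size * self.size
        self.grid = np.full((self.size, self.size), -1, dtype=np.int32)
        self.rows = np.zeros(cap, dtype=np.int32)
        self.cols = np.zeros(cap, dtype=np.int32)
        self.kinds = np.zeros(cap, dtype=np.uint8)
        self.rhos = np.zeros(cap, dtype=np.int16)
        self.n_cells = 0
        self.n_csc = 0

    # -- construction ------------------------------------------------------

    def add_cell(self, kind: CellKind, position: Coordinate, rho: int = 0) -> int:
        """Place a new cell; returns its index.  The site must be vacant."""
        r, c = position
        self._check_bounds(r, c)
        if self.grid[r, c] != -1:
            raise ValueError(f"site {position} already occupied")
        if kind == CellKind.CC and rho < 0:
            raise ValueError("CC rho must be non-negative")
        idx = self.n_cells
        if idx >= self.rows.shape[0]:
            raise ValueError("lattice capacity exhausted")
        self.rows[idx] = r
        self.cols[idx] = c
        self.kinds[idx] = int(kind)
        self.rhos[idx] = rho
        self.grid[r, c] = idx
        self.n_cells += 1
        if kind == CellKind.CSC:
            self.n_csc += 1
        return idx

    # -- queries -----------------------------------------------------------

    @property
    def occupancy_count(self) -> int:
        return self.n_cells

    def cell_at(self, position: Coordinate) -> Optional[Cell]:
        r, c = position
        self._check_bounds(r, c)
        idx = int(self.grid[r, c])
        if idx < 0:
            return None
        return self._view(idx)

    def cells(self) -> Iterator[Cell]:
        for idx in range(self.n_cells):
            yield self._view(idx)

    def _view(self, idx: int) -> Cell:
        return Cell(
            kind=CellKind(int(self.kinds[idx])),
            rho=int(self.rhos[idx]),
            position=(int(self.rows[idx]), int(self.cols[idx])),
            index=idx,
        )

    def _check_bounds(self, r: int, c: int) -> None:
        if not (0 <= r < self.size and 0 <= c < self.size):
            raise IndexError(f"position ({r}, {c}) out of lattice bounds")

    def check_consistency(self) -> None:
        """Assert the grid/arrays agree; used by tests and debug runs."""
        occ = np.argwhere(self.grid >= 0)
        assert len(occ) == self.n_cells, "occupancy count mismatch"
        for r, c in occ:
            idx = self.grid[r, c]
            assert self.rows[idx] == r and self.cols[idx] == c
        assert int(np.sum(self.kinds[: self.n_cells] == 1)) == self.n_csc


# ---------------------------------------------------------------------------
# Compiled kernels.  These are the single implementation of the event rules;
# both the public wrappers and the bulk run loop go through them.
# ---------------------------------------------------------------------------

_EV_SYM = 0
_EV_ASYM = 1
_EV_CC_DIV = 2
_EV_DIED = 3
_EV_MIGRATED = 4
_EV_QUIESCENT = 5


@njit(cache=True)
def _vacant_neighbors(grid, r, c, offs, nbr_r, nbr_c):
    """Fill nbr_r/nbr_c with vacant in-bounds neighbors of (r, c); return count."""
    L = grid.shape[0]
    k = 0
    for j in range(offs.shape[0]):
        rr = r + offs[j, 0]
        cc = c + offs[j, 1]
        if 0 <= rr < L and 0 <= cc < L and grid[rr, cc] == -1:
            nbr_r[k] = rr
            nbr_c[k] = cc
            k += 1
    return k


@njit(cache=True)
def _draw_action(p_prolif, p_mig, has_space, rng):
    """One partitioned uniform draw: 0 proliferate, 1 migrate, 2 quiesce."""
    if not has_space:
        return 2
    u = rng.random()
    if u < p_prolif:
        return 0
    if u < p_prolif + p_mig:
        return 1
    return 2


@njit(cache=True)
def _pick(rng, k):
    j = int(rng.random() * k)
    if j >= k:  # guard against u == 1.0 rounding (cannot occur with random())
        j = k - 1
    return j


@njit(cache=True)
def _process_cell(grid, rows, cols, kinds, rhos, n, idx, dead,
                  p_prolif, p_mig, p_s, rho_max, offs, nbr_r, nbr_c,
                  rng, forced):
    """Process one cell visit; returns (new_n, event_code, edge_contact).

    ``forced`` < 0 draws the action; otherwise the given action code is
    executed unconditionally (used by the single-operation wrappers).
    Daughters are appended at index ``n``; deaths mark ``dead`` and vacate
    the site — the caller compacts afterwards.

    The action is drawn before the neighborhood scan and the scan skipped
    when the draw lands in the quiescence band: per-visit outcomes are
    distributed identically to space-check-first ordering (a cell without
    vacant space is quiescent whatever it draws), and the scan is the per
    visit cost that dominates large runs.
    """
    L = grid.shape[0]
    r = rows[idx]
    c = cols[idx]
    if forced >= 0:
        action = forced
    else:
        u = rng.random()
        if u < p_prolif:
            action = 0
        elif u < p_prolif + p_mig:
            action = 1
        else:
            return n, _EV_QUIESCENT, False
    k = _vacant_neighbors(grid, r, c, offs, nbr_r, nbr_c)
    if k == 0:
        return n, _EV_QUIESCENT, False
    if action == 0:  # proliferation decision
        if kinds[idx] == 1:  # CSC
            symmetric = rng.random() < p_s
            j = _pick(rng, k)
            rr = nbr_r[j]
            cc = nbr_c[j]
            rows[n] = rr
            cols[n] = cc
            if symmetric:
                kinds[n] = 1
                rhos[n] = 0
                ev = _EV_SYM
            else:
                kinds[n] = 0
                rhos[n] = rho_max
                ev = _EV_ASYM
            grid[rr, cc] = n
            edge = rr == 0 or cc == 0 or rr == L - 1 or cc == L - 1
            return n + 1, ev, edge
        # CC
        if rhos[idx] == 0:
            grid[r, c] = -1
            dead[idx] = True
            return n, _EV_DIED, False
        rhos[idx] -= 1
        j = _pick(rng, k)
        rr = nbr_r[j]
        cc = nbr_c[j]
        rows[n] = rr
        cols[n] = cc
        kinds[n] = 0
        rhos[n] = rhos[idx]  # daughter inherits parent's decremented capacity
        grid[rr, cc] = n
        edge = rr == 0 or cc == 0 or rr == L - 1 or cc == L - 1
        return n + 1, _EV_CC_DIV, edge
    # migration: one-site hop to a uniformly chosen vacant neighbor
    j = _pick(rng, k)
    rr = nbr_r[j]
    cc = nbr_c[j]
    grid[r, c] = -1
    rows[idx] = rr
    cols[idx] = cc
    grid[rr, cc] = idx
    edge = rr == 0 or cc == 0 or rr == L - 1 or cc == L - 1
    return n, _EV_MIGRATED, edge


@njit(cache=True)
def _compact(grid, rows, cols, kinds, rhos, n, dead, n0):
    """Remove dead cells (indices < n0) preserving order; return new count."""
    w = 0
    for i in range(n):
        if i < n0 and dead[i]:
            continue
        if w != i:
            rows[w] = rows[i]
            cols[w] = cols[i]
            kinds[w] = kinds[i]
            rhos[w] = rhos[i]
            grid[rows[w], cols[w]] = w
        w += 1
    return w


@njit(cache=True)
def _run_steps(grid, rows, cols, kinds, rhos, n, n_csc,
               max_steps, p_prolif, p_mig, p_s, rho_max, offs,
               stop_at, rng, counts):
    """Advance up to ``max_steps`` asynchronous steps.

    Each step visits every cell alive at the start of the step exactly once
    in a freshly shuffled order (Fisher-Yates on the cell indices); daughters
    born during a step are not visited until the next step.  Stops early once
    the population reaches ``stop_at`` (pass a huge value to disable).

    Returns (n, n_csc, steps_done, edge_contact).  ``counts`` (int64[6]) is
    incremented in place by event code.
    """
    edge = False
    steps_done = 0
    nbr_r = np.empty(8, dtype=np.int64)
    nbr_c = np.empty(8, dtype=np.int64)
    p_act = p_prolif + p_mig
    for _ in range(max_steps):
        n0 = n
        if n0 > 0:
            # fresh random visiting order (Fisher-Yates); uniforms for the
            # shuffle and the per-cell action draws are generated in bulk,
            # which is much cheaper than one Generator call per cell
            perm = np.arange(n0)
            shuffle_u = rng.random(n0)
            for i in range(n0 - 1, 0, -1):
                j = int(shuffle_u[i] * (i + 1))
                if j > i:
                    j = i
                tmp = perm[i]
                perm[i] = perm[j]
                perm[j] = tmp
            action_u = rng.random(n0)
            dead = np.zeros(n0, dtype=np.bool_)
            deaths_before = counts[_EV_DIED]
            for i in range(n0):
                u = action_u[i]
                if u >= p_act:
                    counts[_EV_QUIESCENT] += 1
                    continue
                idx = perm[i]
                if dead[idx]:
                    continue
                forced = 0 if u < p_prolif else 1
                n, ev, e = _process_cell(
                    grid, rows, cols, kinds, rhos, n, idx, dead,
                    p_prolif, p_mig, p_s, rho_max, offs, nbr_r, nbr_c,
                    rng, forced,
                )
                counts[ev] += 1
                if ev == _EV_SYM:
                    n_csc += 1
                edge = edge or e
            if counts[_EV_DIED] > deaths_before:
                n = _compact(grid, rows, cols, kinds, rhos, n, dead, n0)
        steps_done += 1
        if n >= stop_at:
            break
    return n, n_csc, steps_done, edge


# ---------------------------------------------------------------------------
# Public operation wrappers
# ---------------------------------------------------------------------------


def vacant_neighbors(
    lattice: Lattice,
    position: Coordinate,
    offsets: Optional[np.ndarray] = None,
) -> list:
    """All in-bounds, unoccupied sites adjacent to ``position``.

    Out-of-bounds sites are never returned: the lattice boundary behaves as
    permanently occupied (no wraparound).
    """
    r, c = position
    lattice._check_bounds(r, c)
    offs = MOORE if offsets is None else offsets
    nbr_r = np.empty(8, dtype=np.int64)
    nbr_c = np.empty(8, dtype=np.int64)
    k = _vacant_neighbors(lattice.grid, r, c, offs, nbr_r, nbr_c)
    return [(int(nbr_r[j]), int(nbr_c[j])) for j in range(k)]


def draw_action(
    params: SimulationParameters, has_space: bool, rng: np.random.Generator
) -> Action:
    """Draw one action for a cell: quiesce unconditionally without space,
    otherwise a single partitioned uniform draw (proliferate band first)."""
    return Action(_draw_action(params.p_proliferate, params.p_migrate,
                               has_space, rng))


def _resolve_index(lattice: Lattice, cell: Cell) -> int:
    r, c = cell.position
    lattice._check_bounds(r, c)
    idx = int(lattice.grid[r, c])
    if idx < 0:
        raise ValueError(f"no live cell at {cell.position}")
    return idx


def execute_proliferation(
    lattice: Lattice,
    cell: Cell,
    params: SimulationParameters,
    rng: np.random.Generator,
) -> Event:
    """Carry out a proliferation decision for ``cell``.

    CSC: symmetric with probability ``p_s`` (daughter CSC), else asymmetric
    (daughter CC at ``rho_max``); parent unchanged.  CC with ``rho >= 1``:
    both parent and daughter end at ``rho - 1``.  CC at ``rho = 0``: the cell
    dies and its site is vacated.  The daughter occupies a uniformly chosen
    vacant neighbor; calling this with no vacant neighbor is a contract
    violation (the space check gates the action draw upstream).
    """
    idx = _resolve_index(lattice, cell)
    if not vacant_neighbors(lattice, cell.position, params.offsets):
        raise RuntimeError(
            "contract violation: execute_proliferation requires a vacant neighbor"
        )
    return _execute_forced(lattice, idx, params, rng, Action.PROLIFERATE)


def execute_migration(
    lattice: Lattice,
    cell: Cell,
    rng: np.random.Generator,
    params: Optional[SimulationParameters] = None,
) -> Event:
    """Move ``cell`` to a uniformly chosen vacant neighbor (one site hop)."""
    idx = _resolve_index(lattice, cell)
    offs = MOORE if params is None else params.offsets
    if not vacant_neighbors(lattice, cell.position, offs):
        raise RuntimeError(
            "contract violation: execute_migration requires a vacant neighbor"
        )
    p = params if params is not None else SimulationParameters()
    return _execute_forced(lattice, idx, p, rng, Action.MIGRATE)


def _execute_forced(
    lattice: Lattice,
    idx: int,
    params: SimulationParameters,
    rng: np.random.Generator,
    action: Action,
) -> Event:
    n0 = lattice.n_cells
    dead = np.zeros(n0, dtype=np.bool_)
    nbr_r = np.empty(8, dtype=np.int64)
    nbr_c = np.empty(8, dtype=np.int64)
    n, ev, _ = _process_cell(
        lattice.grid, lattice.rows, lattice.cols, lattice.kinds, lattice.rhos,
        n0, idx, dead,
        params.p_proliferate, params.p_migrate, params.p_s, params.rho_max,
        params.offsets, nbr_r, nbr_c, rng, int(action),
    )
    if ev == _EV_DIED:
        n = _compact(
            lattice.grid, lattice.rows, lattice.cols,
            lattice.kinds, lattice.rhos, n, dead, n0,
        )
    lattice.n_cells = int(n)
    if ev == _EV_SYM:
        lattice.n_csc += 1
    return Event(ev)


def step(
    lattice: Lattice, params: SimulationParameters, rng: np.random.Generator
) -> StepSummary:
    """Advance the automaton by one time step (``dt_h`` hours).

    Every cell alive at the start of the step is visited exactly once in a
    freshly shuffled random order against the current lattice state; sites
    freed by earlier deaths in the same step are available to later cells,
    and daughters born during the step are not processed until the next one.
    """
    return run_steps(lattice, params, rng, 1)


def run_steps(
    lattice: Lattice,
    params: SimulationParameters,
    rng: np.random.Generator,
    n_steps: int,
    stop_at: Optional[int] = None,
) -> StepSummary:
    """Advance up to ``n_steps`` steps, stopping early at ``stop_at`` cells."""
    counts = np.zeros(6, dtype=np.int64)
    stop = int(stop_at) if stop_at is not None else np.iinfo(np.int64).max
    n, n_csc, done, edge = _run_steps(
        lattice.grid, lattice.rows, lattice.cols, lattice.kinds, lattice.rhos,
        lattice.n_cells, lattice.n_csc,
        int(n_steps), params.p_proliferate, params.p_migrate,
        params.p_s, params.rho_max, params.offsets, stop, rng, counts,
    )
    lattice.n_cells = int(n)
    lattice.n_csc = int(n_csc)
    return StepSummary(
        divisions=int(counts[_EV_SYM] + counts[_EV_ASYM] + counts[_EV_CC_DIV]),
        symmetric_divisions=int(counts[_EV_SYM]),
        deaths=int(counts[_EV_DIED]),
        migrations=int(counts[_EV_MIGRATED]),
        quiescent=int(counts[_EV_QUIESCENT]),
        steps=int(done),
        edge_contact=bool(edge),
    )
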