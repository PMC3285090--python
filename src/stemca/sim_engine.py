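"""Seeded runs, replicate ensembles, and factorial parameter sweeps.

A run seeds one CSC at the lattice center and advances the automaton until
the population reaches ``max_cells`` (50,000 by default) or simulated time
reaches ``max_time_h`` (5 years).  Total and CSC counts are sampled at
``record_interval_h`` (weekly) ticks, always including t = 0 and the
termination instant, so time-to-threshold is resolved to the hour.
"""

from __future__ import annotations

import enum
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model_core import (
    CellKind,
    Lattice,
    SimulationParameters,
    StepSummary,
    run_steps,
)

__all__ = [
    "Termination",
    "RunResult",
    "SweepResult",
    "run_simulation",
    "run_replicates",
    "sweep",
    "HOURS_PER_WEEK",
]

logger = logging.getLogger("stemca")

HOURS_PER_WEEK = 168.0


class Termination(str, enum.Enum):
    REACHED_MAX_CELLS = "REACHED_MAX_CELLS"
    REACHED_MAX_TIME = "REACHED_MAX_TIME"


@dataclass
class RunResult:
    """Weekly time series and termination status of one seeded run.

    ``weeks`` holds sampling times in weeks; all entries are integral weekly
    ticks except possibly the last, which is the termination instant (hour
    resolution).  ``event_totals`` aggregates division/death/migration tallies
    over the whole run.
    """

    params: SimulationParameters
    seed: int
    weeks: np.ndarray
    total_cells: np.ndarray
    csc_cells: np.ndarray
    termination: Termination
    final_time_h: float
    event_totals: StepSummary = field(default_factory=StepSummary)
    final_lattice: Optional[Lattice] = field(default=None, repr=False)

    @property
    def final_total(self) -> int:
        return int(self.total_cells[-1])

    @property
    def final_csc(self) -> int:
        return int(self.csc_cells[-1])


@dataclass
class SweepResult:
    """Replicate ensembles over a (p_s, mu, rho_max) factorial grid."""

    cells: Dict[Tuple[float, float, int], List[RunResult]]
    n_replicates: int
    base_seed: int

    def runs(self, p_s: float, mu: float, rho_max: int) -> List[RunResult]:
        return self.cells[(p_s, mu, rho_max)]


def run_simulation(
    params: SimulationParameters,
    seed: int,
    keep_lattice: bool = False,
) -> RunResult:
    """Run one seeded simulation from a single central CSC.

    The run stops when the population first reaches ``params.max_cells``
    (``REACHED_MAX_CELLS``) or when ``params.max_time_h`` of simulated time
    has elapsed (``REACHED_MAX_TIME``), whichever comes first.  With
    ``keep_lattice`` the final lattice state is attached to the result (for
    snapshot rendering).
    """
    rng = np.random.default_rng(seed)
    lattice = Lattice(params.lattice_size)
    center = (params.lattice_size // 2, params.lattice_size // 2)
    lattice.add_cell(CellKind.CSC, center)

    steps_per_record = max(1, int(round(params.record_interval_h / params.dt_h)))
    total_steps = int(math.ceil(params.max_time_h / params.dt_h))

    weeks: List[float] = [0.0]
    totals: List[int] = [1]
    cscs: List[int] = [1]
    agg = StepSummary()

    steps_done = 0
    termination = Termination.REACHED_MAX_TIME
    while steps_done < total_steps:
        target = min(steps_done + steps_per_record, total_steps)
        summary = run_steps(
            lattice, params, rng, target - steps_done, stop_at=params.max_cells
        )
        steps_done += summary.steps
        agg.divisions += summary.divisions
        agg.symmetric_divisions += summary.symmetric_divisions
        agg.deaths += summary.deaths
        agg.migrations += summary.migrations
        agg.quiescent += summary.quiescent
        agg.steps += summary.steps
        agg.edge_contact = agg.edge_contact or summary.edge_contact
        weeks.append(steps_done * params.dt_h / HOURS_PER_WEEK)
        totals.append(lattice.n_cells)
        cscs.append(lattice.n_csc)
        if lattice.n_cells >= params.max_cells:
            termination = Termination.REACHED_MAX_CELLS
            break

    if agg.edge_contact:
        logger.warning(
            "run(seed=%d): a cell reached the lattice edge; boundary effects "
            "may bias growth (lattice_size=%d)",
            seed,
            params.lattice_size,
        )

    result = RunResult(
        params=params,
        seed=int(seed),
        weeks=np.asarray(weeks, dtype=float),
        total_cells=np.asarray(totals, dtype=np.int64),
        csc_cells=np.asarray(cscs, dtype=np.int64),
        termination=termination,
        final_time_h=steps_done * params.dt_h,
        event_totals=agg,
        final_lattice=lattice if keep_lattice else None,
    )
    return result


def run_replicates(
    params: SimulationParameters, n: int, base_seed: int
) -> List[RunResult]:
    """``n`` independent runs with seeds ``base_seed .. base_seed + n - 1``."""
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    return [run_simulation(params, base_seed + i) for i in range(n)]


def sweep(
    p_s_values: Sequence[float],
    mu_values: Sequence[float],
    rho_max_values: Sequence[int],
    n: int,
    base_seed: int,
    base_params: Optional[SimulationParameters] = None,
) -> SweepResult:
    """Full factorial sweep over (p_s, mu, rho_max) with ``n`` replicates each.

    Seeds are a pure function of the grid cell and replicate:
    ``seed = base_seed + cell_index * n + replicate`` with cells enumerated
    p_s-major, then mu, then rho_max (the order of
    ``itertools.product(p_s_values, mu_values, rho_max_values)``).  Results
    are therefore independent of execution order and reproducible from the
    grid definition alone.
    """
    if n < 1:
        raise ValueError("replicate count must be >= 1")
    grid = list(itertools.product(p_s_values, mu_values, rho_max_values))
    if not grid:
        raise ValueError("parameter grid must be non-empty")
    template = base_params if base_params is not None else SimulationParameters()
    cells: Dict[Tuple[float, float, int], List[RunResult]] = {}
    for cell_index, (p_s, mu, rho_max) in enumerate(grid):
        params = SimulationParameters(
            rho_max=int(rho_max),
            p_s=float(p_s),
            mu=mu,
            cell_cycle_h=template.cell_cycle_h,
            dt_h=template.dt_h,
            lattice_size=template.lattice_size,
            site_width_um=template.site_width_um,
            max_cells=template.max_cells,
            max_time_h=template.max_time_h,
            record_interval_h=template.record_interval_h,
            neighborhood=template.neighborhood,
        )
        cell_seed = base_seed + cell_index * n
        logger.info(
            "sweep cell %d/%d: p_s=%g mu=%g rho_max=%d (seeds %d..%d)",
            cell_index + 1, len(grid), p_s, mu, rho_max,
            cell_seed, cell_seed + n - 1,
        )
        cells[(p_s, mu, int(rho_max))] = run_replicates(params, n, cell_seed)
    return SweepResult(cells=cells, n_replicates=n, base_seed=base_seed)
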