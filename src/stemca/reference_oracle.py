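"""Independent brute-force oracles for validating the automaton engine.

These routines deliberately share no event-rule code with
:mod:`stemca.model_core`: they implement the type contracts directly
(explicit division-tree enumeration, direct binomial sampling of the action
partition) so the engine can be checked against them on small instances
before sweep-scale results are trusted.
"""

from __future__ import annotations

from typing import List, Optional

import numpy as np

from .model_core import CellKind, Lattice, SimulationParameters, run_steps

__all__ = [
    "max_clone_population",
    "enclosed_dormancy_check",
    "migration_rate_estimate",
]


def max_clone_population(rho: int) -> int:
    """Maximum simultaneous population one CC of capacity ``rho`` can reach.

    Computed by exhaustive synchronous expansion of the division tree under
    unlimited space: every cell with remaining capacity r >= 1 is replaced by
    two cells of capacity r - 1, cells at capacity 0 die on their next
    division attempt.  The peak census over the expansion is returned
    (equal to 2**rho, but obtained by enumeration, not the closed form).
    """
    if rho < 0:
        raise ValueError("rho must be non-negative")
    if rho > 20:
        raise ValueError("enumeration beyond rho = 20 is intentionally refused")
    cells: List[int] = [rho]
    peak = 1
    while cells:
        nxt: List[int] = []
        for r in cells:
            if r >= 1:
                nxt.append(r - 1)
                nxt.append(r - 1)
            # r == 0: dies on the division attempt, no offspring
        cells = nxt
        peak = max(peak, len(cells))
    return peak


def enclosed_dormancy_check(
    steps: int = 10_000,
    seed: int = 0,
    lattice: Optional[Lattice] = None,
    params: Optional[SimulationParameters] = None,
) -> bool:
    """True iff no enclosed cell divides, migrates, or dies over ``steps``.

    The default micro-fixture is a fully packed 5x5 lattice of exhausted
    (rho = 0) CCs with a central CSC: every cell has zero vacant neighbors,
    so the whole population must stay quiescent and constant — spatial
    inhibition makes even death impossible, since a rho = 0 CC only dies on
    a division decision, which requires vacant space.
    """
    if lattice is None:
        lattice = Lattice(5)
        for r in range(5):
            for c in range(5):
                if (r, c) == (2, 2):
                    lattice.add_cell(CellKind.CSC, (r, c))
                else:
                    lattice.add_cell(CellKind.CC, (r, c), rho=0)
    if params is None:
        params = SimulationParameters(
            rho_max=0, p_s=0.1, mu=15, lattice_size=lattice.size,
            max_cells=lattice.size**2,
        )
    before = (lattice.n_cells, lattice.n_csc)
    rng = np.random.default_rng(seed)
    summary = run_steps(lattice, params, rng, steps)
    after = (lattice.n_cells, lattice.n_csc)
    no_events = (
        summary.divisions == 0
        and summary.deaths == 0
        and summary.migrations == 0
    )
    return no_events and before == after


def migration_rate_estimate(mu: float, steps: int, seed: int) -> float:
    """Empirical migration hops/day implied by the action partition.

    Draws ``steps`` independent uniforms and counts those landing in the
    migration band [p_proliferate, p_proliferate + mu/24) — a direct
    Monte-Carlo of the one-hop-per-event binomial rate, written without any
    engine code.  With 24 one-hour steps per day the estimate converges to
    ``mu`` sites/day (binomial SE ~ sqrt(p(1-p)/steps) * 24).
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    p_prolif = 1.0 / 24.0
    p_mig = mu / 24.0
    rng = np.random.default_rng(seed)
    u = rng.random(steps)
    hops = int(np.count_nonzero((u >= p_prolif) & (u < p_prolif + p_mig)))
    return hops / steps * 24.0
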