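"""Ensemble summary statistics: time-to-threshold, t_critical, CSC fractions.

Replicate ensembles are reduced to the quantities used to characterise the
sweep: the mean +/- SEM time for a tumor to reach a population threshold,
the optimum generational life span rho_max per (mu, p_s) pair (the one whose
ensemble reaches the threshold fastest, its mean time being ``t_critical``),
population size at a reference week, and CSC-fraction trajectories.

Censoring: runs that hit the 5-year time bound before the population
threshold are excluded from time statistics and counted separately; their
sizes still contribute to size-at-week statistics (a censored tumor simply
holds its recorded trajectory).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .sim_engine import HOURS_PER_WEEK, RunResult, SweepResult, Termination

__all__ = [
    "ThresholdTime",
    "EnsembleSummary",
    "PairSummary",
    "time_to_threshold",
    "mean_sem",
    "summarize_ensemble",
    "t_critical",
    "population_at",
    "csc_fraction_series",
    "terminal_csc_fraction",
    "build_summary_table",
    "write_table",
]


@dataclass(frozen=True)
class ThresholdTime:
    """Time (weeks) for one run to reach a population threshold."""

    weeks: float
    censored: bool


@dataclass
class EnsembleSummary:
    """Replicate-aggregated statistics for one parameter cell."""

    n: int
    mean_time_weeks: Optional[float]
    sem_time_weeks: Optional[float]
    n_censored: int
    csc_fraction_final_mean: float
    csc_fraction_final_sem: float


@dataclass
class PairSummary:
    """Summary of one (mu, p_s) pair across the rho_max axis.

    ``optimum_rho_max`` is None when every rho_max ensemble is fully censored
    (no t_critical exists for the pair).
    """

    optimum_rho_max: Optional[int]
    t_critical_weeks: Optional[float]
    t_critical_sem_weeks: Optional[float]
    csc_fraction_at_optimum: Optional[float]
    sizes_at_t_critical: Dict[int, float] = field(default_factory=dict)


def time_to_threshold(run: RunResult, threshold: int) -> ThresholdTime:
    """Earliest sampled time at which the population reaches ``threshold``.

    Weekly samples plus the termination instant bound the resolution: a run
    that terminates on reaching ``max_cells`` resolves its own threshold
    crossing to the hour.  Runs that never reach the threshold are censored
    at the 5-year bound (weeks = censoring time).
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    hit = np.nonzero(run.total_cells >= threshold)[0]
    if hit.size:
        return ThresholdTime(weeks=float(run.weeks[hit[0]]), censored=False)
    return ThresholdTime(
        weeks=run.params.max_time_h / HOURS_PER_WEEK, censored=True
    )


def mean_sem(values: Sequence[float]) -> Tuple[float, float]:
    """Sample mean and standard error (sd/sqrt(n), ddof=1; SEM 0 for n=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sem requires at least one value")
    if arr.size == 1:
        return float(arr[0]), 0.0
    return float(arr.mean()), float(arr.std(ddof=1) / math.sqrt(arr.size))


def csc_fraction_series(run: RunResult) -> np.ndarray:
    """CSC count / total population at every sampled week of one run."""
    return run.csc_cells / run.total_cells


def terminal_csc_fraction(run: RunResult) -> float:
    """CSC fraction at the final sample (run termination)."""
    return float(run.csc_cells[-1] / run.total_cells[-1])


def summarize_ensemble(
    runs: Sequence[RunResult], threshold: Optional[int] = None
) -> EnsembleSummary:
    """Aggregate one replicate ensemble.

    Time statistics (mean +/- SEM weeks to ``threshold``, default the runs'
    own ``max_cells``) use uncensored replicates only.
    """
    if not runs:
        raise ValueError("ensemble must contain at least one run")
    thr = threshold if threshold is not None else runs[0].params.max_cells
    times = [time_to_threshold(r, thr) for r in runs]
    uncensored = [t.weeks for t in times if not t.censored]
    if uncensored:
        m, s = mean_sem(uncensored)
    else:
        m = s = None
    fm, fs = mean_sem([terminal_csc_fraction(r) for r in runs])
    return EnsembleSummary(
        n=len(runs),
        mean_time_weeks=m,
        sem_time_weeks=s,
        n_censored=sum(t.censored for t in times),
        csc_fraction_final_mean=fm,
        csc_fraction_final_sem=fs,
    )


def population_at(
    runs: Sequence[RunResult], week: float
) -> Tuple[float, float]:
    """Mean +/- SEM population across replicates at the sampled week nearest
    ``week``; replicates already terminated by then hold their final size."""
    if week < 0:
        raise ValueError("week must be non-negative")
    sizes = []
    for r in runs:
        if week >= r.weeks[-1]:
            sizes.append(float(r.total_cells[-1]))
        else:
            i = int(np.argmin(np.abs(r.weeks - week)))
            sizes.append(float(r.total_cells[i]))
    return mean_sem(sizes)


def t_critical(
    runs_by_rho: Mapping[int, Sequence[RunResult]],
    threshold: Optional[int] = None,
) -> PairSummary:
    """Optimum rho_max and t_critical for one (mu, p_s) pair.

    Selects the rho_max whose ensemble has the minimal mean uncensored time
    to the threshold (ties broken toward the smaller rho_max); its mean +/-
    SEM is t_critical.  Fully censored ensembles are skipped; if every
    ensemble is censored an empty PairSummary (optimum None) is returned.
    ``sizes_at_t_critical`` reports each rho_max ensemble's mean size at the
    weekly sample nearest t_critical.
    """
    if not runs_by_rho:
        raise ValueError("runs_by_rho must be non-empty")
    best_rho: Optional[int] = None
    best: Optional[EnsembleSummary] = None
    summaries: Dict[int, EnsembleSummary] = {}
    for rho in sorted(runs_by_rho):
        s = summarize_ensemble(runs_by_rho[rho], threshold)
        summaries[rho] = s
        if s.mean_time_weeks is None:
            continue
        if best is None or s.mean_time_weeks < best.mean_time_weeks:
            best, best_rho = s, rho
    if best is None or best_rho is None:
        return PairSummary(None, None, None, None, {})
    sizes = {
        rho: population_at(runs_by_rho[rho], best.mean_time_weeks)[0]
        for rho in sorted(runs_by_rho)
    }
    return PairSummary(
        optimum_rho_max=best_rho,
        t_critical_weeks=best.mean_time_weeks,
        t_critical_sem_weeks=best.sem_time_weeks,
        csc_fraction_at_optimum=summaries[best_rho].csc_fraction_final_mean,
        sizes_at_t_critical=sizes,
    )


def _select_pair(
    pair: PairSummary, rhos: Sequence[int]
) -> Optional[Tuple[int, int]]:
    """Pick the (lo, hi) rho_max pair flanking the optimum whose mean sizes
    at t_critical match most closely (the 'similar size, different
    composition' comparison)."""
    opt = pair.optimum_rho_max
    if opt is None:
        return None
    lows = [r for r in rhos if r < opt]
    highs = [r for r in rhos if r > opt]
    if not lows or not highs:
        return None
    best = None
    for lo in lows:
        for hi in highs:
            d = abs(pair.sizes_at_t_critical[lo] - pair.sizes_at_t_critical[hi])
            if best is None or d < best[0]:
                best = (d, lo, hi)
    return (best[1], best[2]) if best else None


def build_summary_table(
    sweep_result: SweepResult, threshold: Optional[int] = None
) -> pd.DataFrame:
    """Sweep-level summary table, one column per (p_s, mu) pair.

    Rows: optimum rho_max, t_critical (mean and SEM weeks), CSC fraction at
    the optimum, and the flanking rho_max pair comparison (matched sizes at
    t_critical, terminal CSC fractions, and times to the threshold for the
    low/high member).  Pairs are n/a (NaN) where no rho_max exists on one
    side of the optimum (e.g. optimum 0 at mu = 0).
    """
    keys = sorted(sweep_result.cells, key=lambda k: (k[0], k[1], k[2]))
    pairs = sorted({(p_s, mu) for p_s, mu, _ in keys})
    columns = {}
    for p_s, mu in pairs:
        rhos = sorted(r for pp, mm, r in keys if (pp, mm) == (p_s, mu))
        runs_by_rho = {r: sweep_result.cells[(p_s, mu, r)] for r in rhos}
        ps = t_critical(runs_by_rho, threshold)
        col: Dict[str, object] = {
            "optimum_rho_max": ps.optimum_rho_max,
            "t_critical_weeks": ps.t_critical_weeks,
            "t_critical_sem_weeks": ps.t_critical_sem_weeks,
            "csc_fraction_at_optimum": ps.csc_fraction_at_optimum,
        }
        sel = _select_pair(ps, rhos)
        if sel is None:
            col.update(
                pair_low_rho=np.nan, pair_high_rho=np.nan,
                pair_size_low=np.nan, pair_size_high=np.nan,
                pair_csc_fraction_low=np.nan, pair_csc_fraction_high=np.nan,
                pair_weeks_low=np.nan, pair_weeks_high=np.nan,
            )
        else:
            lo, hi = sel
            s_lo = summarize_ensemble(runs_by_rho[lo], threshold)
            s_hi = summarize_ensemble(runs_by_rho[hi], threshold)
            col.update(
                pair_low_rho=lo,
                pair_high_rho=hi,
                pair_size_low=ps.sizes_at_t_critical[lo],
                pair_size_high=ps.sizes_at_t_critical[hi],
                pair_csc_fraction_low=s_lo.csc_fraction_final_mean,
                pair_csc_fraction_high=s_hi.csc_fraction_final_mean,
                pair_weeks_low=s_lo.mean_time_weeks,
                pair_weeks_high=s_hi.mean_time_weeks,
            )
        columns[f"p_s={p_s:g},mu={mu:g}"] = col
    return pd.DataFrame(columns)


def write_table(table: pd.DataFrame, path: str) -> None:
    """Export the summary table as TSV (``.tsv``) or JSON (``.json``)."""
    path = str(path)
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(json.loads(table.to_json()), fh, indent=2)
    else:
        table.to_csv(path, sep="\t", index_label="statistic")
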