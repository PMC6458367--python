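"""Simulation studies of criterion behaviour.

Three experiment designs, all fully seeded:

* *selection frequency* — fix a true order ``h_true``, repeatedly draw
  trajectory sets from a random network, let every criterion pick an
  order from a candidate ladder, and tabulate how often each order is
  chosen;
* *delta distributions* — the distribution, across replicates, of
  ``Criterion(h) - Criterion(h_true)`` for each non-true candidate
  (positive values mean the true model is favoured);
* *free-throw power analysis* — the same selection-frequency design but
  with seasons of simulated free-throw games as the data-generating
  process, used to ask how often a memory-free or one-step-memory
  shooter would be correctly identified at a realistic season size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .criteria import CRITERIA, criteria_values
from .dirichlet import DirichletPrior
from .simulate import (
    FreeThrowConfig,
    generate_network,
    network_symbols,
    sample_trajectories,
    simulate_season,
)
from .trajectories import TrajectorySet, count_all_orders

__all__ = [
    "SelectionFrequencyTable",
    "DeltaDistribution",
    "selection_experiment",
    "delta_experiment",
    "power_analysis_freethrow",
]


@dataclass
class SelectionFrequencyTable:
    """Fraction of replicates in which each candidate order was selected.

    ``freq`` has one row per criterion and one column per candidate
    order; every row sums to 1.
    """

    freq: pd.DataFrame
    metadata: dict

    def to_csv(self, path) -> None:
        self.freq.to_csv(path, index_label="criterion")


@dataclass
class DeltaDistribution:
    """Replicate-level samples of ``Criterion(h) - Criterion(h_true)``."""

    samples: dict[str, dict[int, np.ndarray]]
    h_true: int
    metadata: dict

    def summary(self) -> pd.DataFrame:
        rows = []
        for crit, per_h in self.samples.items():
            for h, arr in per_h.items():
                rows.append(
                    {
                        "criterion": crit,
                        "h": h,
                        "min": float(arr.min()),
                        "mean": float(arr.mean()),
                        "max": float(arr.max()),
                        "frac_nonpositive": float(np.mean(arr <= 0)),
                    }
                )
        return pd.DataFrame(rows)


def _criteria_by_order(
    trajs: TrajectorySet,
    h_candidates: list[int],
    prior: DirichletPrior | None,
    k_mode: str,
    pad: str | None = None,
) -> dict[int, dict[str, float]]:
    tables = count_all_orders(trajs, max(h_candidates), pad)
    return {h: criteria_values(tables[h], prior, k_mode) for h in h_candidates}


def _select(values_by_order, h_candidates, criterion) -> int:
    """Argmin over candidates; ties go to the smaller order (candidates ascending)."""
    best_h, best_v = None, np.inf
    for h in h_candidates:
        v = values_by_order[h][criterion]
        if np.isnan(v):
            continue
        if v < best_v:
            best_h, best_v = h, v
    if best_h is None:
        raise ValueError(f"criterion {criterion!r} undefined for every candidate")
    return best_h


def _tally(
    trajectory_sets,
    h_candidates: list[int],
    prior: DirichletPrior | None,
    k_mode: str,
    criteria,
    pad: str | None = None,
) -> pd.DataFrame:
    h_candidates = sorted(h_candidates)
    criteria = list(criteria)
    counts = {c: {h: 0 for h in h_candidates} for c in criteria}
    n = 0
    for trajs in trajectory_sets:
        vals = _criteria_by_order(trajs, h_candidates, prior, k_mode, pad)
        for c in list(criteria):
            try:
                counts[c][_select(vals, h_candidates, c)] += 1
            except ValueError:
                # criterion undefined for every candidate (e.g. LHO at J=1)
                warnings.warn(f"criterion {c!r} undefined; dropped from the table")
                criteria.remove(c)
        n += 1
    freq = pd.DataFrame(
        {h: [counts[c][h] / n for c in criteria] for h in h_candidates},
        index=criteria,
    )
    return freq


def selection_experiment(
    M: int,
    h_true: int,
    J: int,
    h_candidates: list[int] = (0, 1, 2, 3, 4, 5),
    replicates: int = 2000,
    seed=0,
    network_mode: str = "fixed_network",
    prior: DirichletPrior | None = None,
    k_mode: str = "literal",
    criteria=CRITERIA,
    max_len: int = 10**6,
) -> SelectionFrequencyTable:
    """How often each criterion selects each order on random-network data.

    ``fixed_network`` (default) draws one network for the whole run and
    resamples only the trajectory sets; ``fresh_network`` redraws the
    network each replicate, which spreads the selection frequencies over
    network-to-network variability.

    Candidate orders are fitted with histories padded by the designated
    start state (known to precede every trajectory), so every context
    lies in the ordinary order-``h`` context set and the literal
    ``M^h (M-1)`` parameter count applies exactly.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if network_mode not in ("fixed_network", "fresh_network"):
        raise ValueError(f"unknown network_mode {network_mode!r}")
    h_candidates = sorted(h_candidates)
    ss = np.random.SeedSequence(seed)
    net_seed, sample_seed = ss.spawn(2)
    rng = np.random.default_rng(sample_seed)
    net_rng = np.random.default_rng(net_seed)

    def _sets():
        if network_mode == "fixed_network":
            net = generate_network(M, h_true, net_rng)
            for _ in range(replicates):
                yield sample_trajectories(net, J, rng, max_len)
        else:
            for _ in range(replicates):
                net = generate_network(M, h_true, net_rng)
                yield sample_trajectories(net, J, rng, max_len)

    freq = _tally(_sets(), h_candidates, prior, k_mode, criteria, pad=network_symbols(M)[0])
    meta = {
        "M": M,
        "h_true": h_true,
        "J": J,
        "h_candidates": h_candidates,
        "replicates": replicates,
        "seed": seed,
        "network_mode": network_mode,
        "k_mode": k_mode,
    }
    return SelectionFrequencyTable(freq, meta)


def delta_experiment(
    M: int,
    h_true: int,
    J: int,
    h_candidates: list[int] = (0, 1, 2, 3),
    replicates: int = 2000,
    seed=0,
    prior: DirichletPrior | None = None,
    k_mode: str = "literal",
    criteria=CRITERIA,
    max_len: int = 10**6,
) -> DeltaDistribution:
    """Distributions of each criterion relative to its value at the true order."""
    h_candidates = sorted(h_candidates)
    if h_true not in h_candidates:
        raise ValueError("h_true must be among the candidates")
    ss = np.random.SeedSequence(seed)
    net_seed, sample_seed = ss.spawn(2)
    net = generate_network(M, h_true, np.random.default_rng(net_seed))
    rng = np.random.default_rng(sample_seed)

    others = [h for h in h_candidates if h != h_true]
    samples = {c: {h: np.empty(replicates) for h in others} for c in criteria}
    for r in range(replicates):
        trajs = sample_trajectories(net, J, rng, max_len)
        vals = _criteria_by_order(trajs, h_candidates, prior, k_mode, pad=net.start)
        for c in criteria:
            ref = vals[h_true][c]
            for h in others:
                samples[c][h][r] = vals[h][c] - ref
    meta = {
        "M": M,
        "h_true": h_true,
        "J": J,
        "h_candidates": h_candidates,
        "replicates": replicates,
        "seed": seed,
        "k_mode": k_mode,
    }
    return DeltaDistribution(samples, h_true, meta)


def power_analysis_freethrow(
    cfg: FreeThrowConfig,
    h_candidates: list[int] = (0, 1, 2, 3),
    replicates: int = 1000,
    seed=0,
    prior: DirichletPrior | None = None,
    k_mode: str = "contexts",
    criteria=CRITERIA,
) -> SelectionFrequencyTable:
    """Selection frequencies over repeatedly simulated free-throw seasons.

    Each replicate simulates a fresh season under ``cfg`` and lets every
    criterion pick an order.  With a memory-free shooter the column at
    ``h = 0`` is the probability of correctly concluding "no memory";
    with a Markov shooter the ``h = 1`` column is the power to detect
    the dependence.  Parameter counting defaults to observed contexts,
    the natural convention for boundary-padded free-throw strings.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    def _sets():
        for _ in range(replicates):
            yield simulate_season(cfg, rng)

    freq = _tally(_sets(), sorted(h_candidates), prior, k_mode, criteria)
    meta = {
        "games": cfg.games,
        "mean_attempts": cfg.mean_attempts,
        "process": repr(cfg.process),
        "h_candidates": sorted(h_candidates),
        "replicates": replicates,
        "seed": seed,
        "k_mode": k_mode,
    }
    return SelectionFrequencyTable(freq, meta)
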