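"""Cross-scenario risk synthesis: totals, ranks, and median ranks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .scenarios import CORE_SCENARIOS

__all__ = ["RiskSummary", "rank_species", "median_rank", "summarize_risk"]


@dataclass(frozen=True)
class RiskSummary:
    """Per-species risk across scenarios.

    ``total_risk`` sums the six core-scenario integrals; sub-scenario
    integrals (juvenile offtake, egg harvest) are carried but excluded
    from the total and the median rank. Rank 1 = most resilient.
    """

    species: str
    integrals: dict
    total_risk: float
    ranks: dict
    median_rank: float


def rank_species(
    integrals_by_species: Mapping[str, float], scenario: str | None = None
) -> dict[str, float]:
    """Ascending ranks of the risk integral (ties averaged).

    Lower rank = lower integral = higher resilience.
    """
    if len(integrals_by_species) < 2:
        raise ValueError("ranking needs at least 2 species")
    names = list(integrals_by_species)
    vals = np.array([integrals_by_species[n] for n in names], dtype=float)
    if np.any(~np.isfinite(vals)):
        bad = [n for n, v in zip(names, vals) if not np.isfinite(v)]
        raise ValueError(f"missing or non-finite integral for: {bad} (scenario={scenario})")
    ranks = rankdata(vals, method="average")
    return dict(zip(names, ranks.tolist()))


def median_rank(ranks_across_scenarios: Mapping[str, float]) -> float:
    """Median of the six core-scenario ranks for one species."""
    missing = [s for s in CORE_SCENARIOS if s not in ranks_across_scenarios]
    if missing:
        raise ValueError(f"missing core scenarios: {missing}")
    return float(np.median([ranks_across_scenarios[s] for s in CORE_SCENARIOS]))


def summarize_risk(
    integrals: Mapping[str, Mapping[str, float]],
) -> tuple[list[RiskSummary], pd.DataFrame]:
    """Build per-species summaries from {scenario: {species: integral}}.

    Returns the summaries plus a tidy one-row-per-species frame with
    integral and rank columns per scenario, the summed core risk, and the
    median core rank.
    """
    scen_names = list(integrals)
    core_present = [s for s in CORE_SCENARIOS if s in scen_names]
    if core_present != list(CORE_SCENARIOS):
        missing = set(CORE_SCENARIOS) - set(core_present)
        raise ValueError(f"core scenarios missing from integrals: {sorted(missing)}")
    species = list(next(iter(integrals.values())))
    for s in scen_names:
        if set(integrals[s]) != set(species):
            raise ValueError(f"scenario {s!r} has a different species set")

    ranks = {s: rank_species(integrals[s], s) for s in scen_names}
    summaries = []
    rows = []
    for sp in species:
        per_scen = {s: float(integrals[s][sp]) for s in scen_names}
        per_rank = {s: ranks[s][sp] for s in scen_names}
        total = float(sum(per_scen[s] for s in CORE_SCENARIOS))
        med = median_rank(per_rank)
        summaries.append(
            RiskSummary(
                species=sp,
                integrals=per_scen,
                total_risk=total,
                ranks=per_rank,
                median_rank=med,
            )
        )
        row = {"species": sp, "total_risk": total, "median_rank": med}
        for s in scen_names:
            row[f"integral_{s}"] = per_scen[s]
            row[f"rank_{s}"] = per_rank[s]
        rows.append(row)
    return summaries, pd.DataFrame(rows)
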