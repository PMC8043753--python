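"""Perturbation scenarios and quasi-extinction sweeps.

Each scenario perturbs one vital rate or process over a progressive
intensity grid; for each grid point the probability of quasi-extinction
is estimated from the stochastic ensemble, and the area under the
resulting curve (over a min-max normalized intensity axis) summarizes a
species' extinction risk under that scenario.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .demography_core import SpeciesParams
from .dynamics import SimConfig, quasi_extinction_probability

__all__ = [
    "PerturbationSetting",
    "QuasiExtinctionCurve",
    "SCENARIO_KINDS",
    "CORE_SCENARIOS",
    "PROPORTIONAL_SCENARIOS",
    "DROMAIUS_NEST_SUCCESS",
    "DROMAIUS_HATCHING_PROB",
    "egg_production_fraction",
    "daughter_egg_rate",
    "egg_harvest_fertility",
    "make_scenario",
    "find_unit_extinction_intensity",
    "sweep",
    "integrate_curve",
]

SCENARIO_KINDS = (
    "none",
    "juvenile_survival",
    "fertility",
    "all_survival",
    "offtake",
    "offtake_juvenile",
    "egg_harvest",
    "cat_frequency",
    "cat_magnitude",
)

#: The six scenarios entering total risk and the median susceptibility rank.
CORE_SCENARIOS = (
    "juvenile_survival",
    "fertility",
    "all_survival",
    "offtake",
    "cat_frequency",
    "cat_magnitude",
)

#: Scenarios whose intensity is a proportional reduction on [0, 1].
PROPORTIONAL_SCENARIOS = ("juvenile_survival", "fertility", "all_survival")

# Emu reproductive components used to size the harvestable egg pool.
DROMAIUS_NEST_SUCCESS = 0.406
DROMAIUS_HATCHING_PROB = 0.419


@dataclass(frozen=True)
class PerturbationSetting:
    """One grid point of one scenario.

    ``intensity`` is interpreted per kind: proportion reduced for the
    proportional scenarios, females removed per year for offtake,
    eggs harvested per female per year for egg_harvest, a frequency
    multiplier (>= 1) for cat_frequency, and a severity for
    cat_magnitude.
    """

    kind: str
    intensity: float
    egg_fraction: float | None = None
    freq_mult_max: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.kind in PROPORTIONAL_SCENARIOS and self.intensity > 1.0 + 1e-12:
            raise ValueError(f"{self.kind}: proportional intensity must lie in [0, 1]")
        if self.kind == "cat_magnitude" and self.intensity > 1.0 + 1e-12:
            raise ValueError("cat_magnitude severity must lie in [0, 1]")


@dataclass(frozen=True)
class QuasiExtinctionCurve:
    """Pr(E_q) as a function of perturbation intensity, plus its area."""

    species: str
    kind: str
    intensities: np.ndarray
    pr_eq: np.ndarray
    integral: float
    raw_integral: float

    def __post_init__(self) -> None:
        x = np.asarray(self.intensities, dtype=float)
        p = np.asarray(self.pr_eq, dtype=float)
        if x.shape != p.shape:
            raise ValueError("intensities and pr_eq must have the same length")
        if np.any(np.diff(x) <= 0):
            raise ValueError("intensities must be strictly increasing")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("pr_eq values must lie in [0, 1]")
        object.__setattr__(self, "intensities", x)
        object.__setattr__(self, "pr_eq", p)


def egg_production_fraction(
    nest_success: float = DROMAIUS_NEST_SUCCESS,
    hatching_prob: float = DROMAIUS_HATCHING_PROB,
) -> float:
    """Proportion of total fecundity contributed by individual egg
    production: nest success x hatching probability (rounded to 2 dp)."""
    return round(nest_success * hatching_prob, 2)


def daughter_egg_rate(eggs_per_female: float) -> float:
    """Eggs resulting in daughters under a 1:1 sex ratio."""
    if eggs_per_female < 0:
        raise ValueError("egg production must be non-negative")
    return eggs_per_female / 2.0


def egg_harvest_fertility(
    total_fertility: float, eggs_removed: float, egg_fraction: float
) -> float:
    """Realized daughter fertility after harvesting eggs.

    The harvestable daughter-egg pool is ``egg_fraction`` of total
    fertility; harvested eggs count both sexes, so removals are halved
    under a 1:1 sex ratio. Fertility never drops below the un-harvestable
    component.
    """
    if total_fertility < 0 or eggs_removed < 0:
        raise ValueError("fertility and harvest must be non-negative")
    if not (0.0 <= egg_fraction <= 1.0):
        raise ValueError("egg_fraction must lie in [0, 1]")
    daughter_pool = egg_fraction * total_fertility
    return total_fertility - min(daughter_egg_rate(eggs_removed), daughter_pool)


def _proportional_grid(step: float = 0.05) -> np.ndarray:
    n = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, n + 1)


def make_scenario(
    kind: str,
    step: float = 0.05,
    n_points: int = 20,
    max_intensity: float | None = None,
    egg_fraction: float | None = None,
    freq_mult_max: float | None = None,
) -> list[PerturbationSetting]:
    """Build the intensity grid for one scenario.

    Proportional scenarios sweep 0..1 in ``step`` increments. Unbounded
    scenarios (offtake, offtake_juvenile, egg_harvest, cat_frequency)
    need ``max_intensity`` — usually from
    :func:`find_unit_extinction_intensity` — and use ``n_points``
    log-spaced points (offtake grids are prefixed with 0).
    cat_magnitude sweeps severity from the 0.5 baseline to 1 and carries
    the per-iteration frequency-multiplier range.
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}")
    if kind == "none":
        return [PerturbationSetting("none", 0.0)]
    if kind in PROPORTIONAL_SCENARIOS:
        return [PerturbationSetting(kind, float(x)) for x in _proportional_grid(step)]
    if kind == "cat_magnitude":
        sev = np.linspace(0.5, 1.0, max(2, int(round(0.5 / step)) + 1))
        return [
            PerturbationSetting(kind, float(s), freq_mult_max=freq_mult_max) for s in sev
        ]
    if kind == "cat_frequency":
        if max_intensity is None or max_intensity <= 1.0:
            raise ValueError("cat_frequency needs max_intensity > 1 (multiplier sweep)")
        grid = np.geomspace(1.0, max_intensity, n_points)
        return [PerturbationSetting(kind, float(x)) for x in grid]
    if kind in ("offtake", "offtake_juvenile", "egg_harvest"):
        if max_intensity is None or max_intensity <= 0:
            raise ValueError(f"{kind} needs a positive max_intensity")
        lo = max_intensity / 10.0 ** max(2, n_points // 8)
        grid = np.concatenate([[0.0], np.geomspace(lo, max_intensity, n_points - 1)])
        return [
            PerturbationSetting(kind, float(x), egg_fraction=egg_fraction) for x in grid
        ]
    raise AssertionError("unreachable")


def find_unit_extinction_intensity(
    params: SpeciesParams,
    config: SimConfig,
    kind: str,
    start: float = 1.0,
    search_iterations: int | None = None,
    rel_tol: float = 0.05,
    max_doublings: int = 40,
    egg_fraction: float | None = None,
) -> float:
    """Smallest intensity at which every run goes quasi-extinct.

    Doubling search followed by bisection on Pr(E_q) = 1 for the
    unbounded scenarios (offtake counts, catastrophe-frequency
    multipliers, egg-harvest rates). ``search_iterations`` lets the
    search run on a thinner ensemble than the final sweep.
    """
    if kind not in ("offtake", "offtake_juvenile", "egg_harvest", "cat_frequency"):
        raise ValueError(f"{kind!r} has a bounded intensity range")
    cfg = config if search_iterations is None else config.updated(iterations=search_iterations)

    def all_extinct(x: float) -> bool:
        p = PerturbationSetting(kind, x, egg_fraction=egg_fraction)
        return quasi_extinction_probability(params, cfg, p) >= 1.0

    hi = max(start, 1e-6)
    lo = 0.0
    for _ in range(max_doublings):
        if all_extinct(hi):
            break
        lo = hi
        hi *= 2.0
    else:
        raise RuntimeError(
            f"{params.name}/{kind}: no unit-extinction intensity found below {hi}"
        )
    # bisect down to rel_tol
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if all_extinct(mid):
            hi = mid
        else:
            lo = mid
    return hi


def sweep(
    params: SpeciesParams,
    config: SimConfig,
    scenario_settings: list[PerturbationSetting],
) -> QuasiExtinctionCurve:
    """Estimate Pr(E_q) at every grid point of one scenario.

    All grid points share the same base seed (common random numbers), so
    curves are monotone in intensity up to genuine Monte-Carlo noise.
    """
    if not scenario_settings:
        raise ValueError("scenario_settings is empty")
    kinds = {s.kind for s in scenario_settings}
    if len(kinds) > 1:
        raise ValueError(f"mixed scenario kinds in one sweep: {sorted(kinds)}")
    xs = np.array([s.intensity for s in scenario_settings], dtype=float)
    prs = np.array(
        [quasi_extinction_probability(params, config, s) for s in scenario_settings]
    )
    integral, raw = _integrals(xs, prs)
    return QuasiExtinctionCurve(
        species=params.name,
        kind=kinds.pop(),
        intensities=xs,
        pr_eq=prs,
        integral=integral,
        raw_integral=raw,
    )


def _integrals(xs: np.ndarray, prs: np.ndarray) -> tuple[float, float]:
    if len(xs) < 2:
        raise ValueError("need at least 2 grid points to integrate")
    span = xs[-1] - xs[0]
    if span <= 0:
        raise ValueError("degenerate intensity grid")
    norm_x = (xs - xs[0]) / span
    return float(np.trapezoid(prs, norm_x)), float(np.trapezoid(prs, xs))


def integrate_curve(curve: QuasiExtinctionCurve, normalized: bool = True) -> float:
    """Trapezoidal area under the quasi-extinction curve.

    With ``normalized`` (default) the intensity axis is min-max scaled to
    [0, 1] first, so areas are comparable across scenarios with
    different intensity units; the result then lies in [0, 1].
    """
    norm, raw = _integrals(curve.intensities, curve.pr_eq)
    return norm if normalized else raw
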