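"""Stochastic projection engine.

Projects age-structured populations forward in yearly steps with
demographic stochasticity (binomial survival, Poisson recruitment),
compensatory density feedback on survival, and generation-scaled
catastrophic die-offs. All heavy paths are vectorized across Monte-Carlo
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import numpy as np
from scipy.optimize import brentq

from .demography_core import (
    DEFAULT_AREA_KM2,
    DemographyError,
    LeslieModel,
    PopulationVector,
    SpeciesParams,
    build_leslie,
    initial_population,
    leslie_matrix,
)

__all__ = [
    "SimConfig",
    "Trajectory",
    "ProjectionResult",
    "density_feedback",
    "calibrate_feedback",
    "step_stochastic",
    "apply_catastrophe",
    "project",
    "quasi_extinction_probability",
    "round_half_up",
    "DEFAULT_CAT_PROB_PER_GENERATION",
    "DEFAULT_CAT_SEVERITY",
]

#: Baseline probability of a catastrophic die-off per generation
#: (Reed et al.-style severe-catastrophe frequency).
DEFAULT_CAT_PROB_PER_GENERATION = 0.14
#: Baseline proportional mortality of a catastrophe (~50% die-off).
DEFAULT_CAT_SEVERITY = 0.5


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (min 1).

    Used wherever a generation length enters a time-step count.
    """
    return max(1, int(np.floor(x + 0.5)))


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the stochastic projection.

    Horizon is ``horizon_generations * round(G)`` years with the first
    ``burnin_generations * round(G)`` years dropped as burn-in.
    """

    iterations: int = 10_000
    area_km2: float = DEFAULT_AREA_KM2
    eq_threshold_females: int = 50
    horizon_generations: int = 40
    burnin_generations: int = 1
    seed: int = 0
    cat_prob_per_generation: float = DEFAULT_CAT_PROB_PER_GENERATION
    cat_severity: float = DEFAULT_CAT_SEVERITY
    density_feedback_on: bool = True
    feedback_theta: float = 1.0
    demographic_stochasticity: bool = True
    catastrophes_on: bool = True
    census: str = "pre"
    g_method: str = "mean_age_mothers"
    first_passage: bool = False
    record_structure: bool = False

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 <= self.cat_severity <= 1.0):
            raise ValueError("cat_severity must lie in [0, 1]")
        if not (0.0 <= self.cat_prob_per_generation <= 1.0):
            raise ValueError("cat_prob_per_generation must lie in [0, 1]")
        if self.eq_threshold_females < 1:
            raise ValueError("eq_threshold_females must be >= 1")

    def updated(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Trajectory:
    """One stochastic run: yearly totals after burn-in removal."""

    totals: np.ndarray
    final_total: float
    quasi_extinct: bool
    structure: np.ndarray | None = None


@dataclass(frozen=True)
class ProjectionResult:
    """Ensemble summary of a projection run."""

    species: str
    finals: np.ndarray
    quasi_extinct: np.ndarray
    pr_eq: float
    totals: np.ndarray | None = None
    horizon_years: int = 0
    burnin_years: int = 0

    def trajectories(self) -> list[Trajectory]:
        if self.totals is None:
            raise ValueError("projection was run without recording totals")
        return [
            Trajectory(
                totals=self.totals[i],
                final_total=float(self.finals[i]),
                quasi_extinct=bool(self.quasi_extinct[i]),
            )
            for i in range(self.totals.shape[0])
        ]


# ---------------------------------------------------------------------------
# density feedback


def density_feedback(total_n, K: float, c: float, theta: float = 1.0):
    """Compensatory survival multiplier 1 / (1 + c * (N/K)^theta).

    Equals 1 as N -> 0, strictly decreasing in N, and equals the
    calibrated stationarity multiplier at N = K.
    """
    if not K > 0:
        raise ValueError("carrying capacity K must be positive")
    if c < 0:
        raise ValueError("feedback strength c must be non-negative")
    n = np.asarray(total_n, dtype=float)
    out = 1.0 / (1.0 + c * (n / K) ** theta)
    return float(out) if np.isscalar(total_n) else out


def _lambda_at_multiplier(params: SpeciesParams, mult: float, census: str) -> float:
    scaled = params.with_rates(survival=np.clip(params.survival * mult, 0.0, 1.0))
    return build_leslie(scaled, census=census).lam


_FEEDBACK_CACHE: dict[tuple, float] = {}


def calibrate_feedback(
    params: SpeciesParams, census: str = "pre", tol: float = 1e-10
) -> float:
    """Feedback strength c making the deterministic model stationary at K.

    Solves lambda(survival * mult) = 1 for the survival multiplier mult*
    and returns c = 1/mult* - 1, so the multiplier at N = K is exactly
    mult*. Species that cannot reach lambda >= 1 even unregulated get
    c = 0 (feedback cannot boost a declining population).
    """
    key = (
        params.name,
        params.survival.tobytes(),
        params.fertility.tobytes(),
        params.terminal_self_loop,
        census,
    )
    cached = _FEEDBACK_CACHE.get(key)
    if cached is not None:
        return cached
    lam0 = _lambda_at_multiplier(params, 1.0, census)
    if lam0 <= 1.0:
        c = 0.0
    else:
        f = lambda m: _lambda_at_multiplier(params, m, census) - 1.0
        lo = 1e-9
        if f(lo) >= 0:
            raise DemographyError(f"{params.name}: cannot calibrate density feedback")
        mult_star = brentq(f, lo, 1.0, xtol=tol)
        c = 1.0 / mult_star - 1.0
    _FEEDBACK_CACHE[key] = c
    return c


# ---------------------------------------------------------------------------
# elementary stochastic kernels (single-vector API)


def step_stochastic(
    n: PopulationVector,
    model: LeslieModel,
    feedback_multiplier: float,
    rng: np.random.Generator,
) -> PopulationVector:
    """One stochastic yearly transition of a single population vector.

    Survivors of each age class are binomial with probability
    S_x * feedback_multiplier; recruits are Poisson with mean equal to the
    feedback-adjusted first-row contribution, so the expectation of the
    step is the deterministic (scaled) matrix product.
    """
    if not (0.0 < feedback_multiplier <= 1.0):
        raise ValueError("feedback_multiplier must lie in (0, 1]")
    counts = np.asarray(np.round(n.n), dtype=np.int64)
    if np.any(counts < 0):
        raise DemographyError("negative abundances in population vector")
    new = _step_matrix(
        counts[None, :],
        model.params,
        model.matrix[0],
        np.array([feedback_multiplier]),
        rng,
        stochastic=True,
    )[0]
    return PopulationVector(new.astype(float))


def apply_catastrophe(
    n: PopulationVector,
    prob_per_year: float,
    severity: float,
    rng: np.random.Generator,
) -> PopulationVector:
    """Bernoulli catastrophe: with probability ``prob_per_year`` every age
    class is binomially thinned by the factor (1 - severity)."""
    if not (0.0 <= prob_per_year <= 1.0) or not (0.0 <= severity <= 1.0):
        raise ValueError("prob_per_year and severity must lie in [0, 1]")
    if rng.random() >= prob_per_year:
        return n
    counts = np.asarray(np.round(n.n), dtype=np.int64)
    return PopulationVector(rng.binomial(counts, 1.0 - severity).astype(float))


# ---------------------------------------------------------------------------
# vectorized ensemble engine

def _step_matrix(
    N: np.ndarray,
    params: SpeciesParams,
    first_row: np.ndarray,
    mult: np.ndarray,
    rng: np.random.Generator,
    stochastic: bool,
) -> np.ndarray:
    """Advance an (iterations, ages) abundance matrix one year.

    ``mult`` is the per-iteration survival multiplier. Every matrix entry
    carries exactly one survival factor under the pre-breeding census, so
    the whole transition scales with ``mult``.
    """
    surv_p = np.clip(params.survival * mult[:, None], 0.0, 1.0)
    recruit_mean = (N * first_row[None, :]).sum(axis=1) * mult
    out = np.zeros_like(N)
    if stochastic:
        survivors = rng.binomial(N, surv_p)
        out[:, 1:] = survivors[:, :-1]
        if params.terminal_self_loop:
            out[:, -1] += survivors[:, -1]
        out[:, 0] = rng.poisson(np.clip(recruit_mean, 0.0, None))
    else:
        survivors = N * surv_p
        out = out.astype(float)
        out[:, 1:] = survivors[:, :-1]
        if params.terminal_self_loop:
            out[:, -1] += survivors[:, -1]
        out[:, 0] = np.clip(recruit_mean, 0.0, None)
    return out


def _apply_offtake(
    N: np.ndarray, removal: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Remove a fixed per-age number of females, capped by availability.

    ``removal`` is a length-(ages) real vector; fractional parts are
    resolved by Bernoulli rounding so the expectation matches exactly.
    """
    base = np.floor(removal)
    frac = removal - base
    take = base[None, :] + (rng.random(N.shape) < frac[None, :])
    return np.maximum(N - take.astype(N.dtype), 0)


def project(
    params: SpeciesParams,
    config: SimConfig,
    perturbation=None,
    return_result: bool = False,
):
    """Run the full stochastic projection for one species.

    Starts every iteration at n0 = A*D*M*w, steps yearly with density
    feedback, catastrophes, and the requested perturbation, and removes
    the first round(G) * burnin_generations years as burn-in. Returns a
    list of :class:`Trajectory` (or a :class:`ProjectionResult` when
    ``return_result`` is true, which is cheaper for large ensembles).
    """
    from .scenarios import PerturbationSetting  # local import to avoid cycle

    if perturbation is not None and not isinstance(perturbation, PerturbationSetting):
        raise TypeError("perturbation must be a PerturbationSetting or None")
    result = _project_result(params, config, perturbation)
    if return_result:
        return result
    return result.trajectories()


def _perturbed_params(params: SpeciesParams, perturbation) -> SpeciesParams:
    """Apply vital-rate perturbations; offtake/catastrophe kinds pass through."""
    if perturbation is None or perturbation.kind == "none":
        return params
    kind, x = perturbation.kind, perturbation.intensity
    if kind == "juvenile_survival":
        s = params.survival.copy()
        s[: params.alpha] *= 1.0 - x
        return params.with_rates(survival=s)
    if kind == "all_survival":
        return params.with_rates(survival=params.survival * (1.0 - x))
    if kind == "fertility":
        return params.with_rates(fertility=params.fertility * (1.0 - x))
    if kind == "egg_harvest":
        from .scenarios import egg_harvest_fertility

        frac = perturbation.egg_fraction
        m = params.fertility.copy()
        for i in range(len(m)):
            if m[i] > 0:
                m[i] = egg_harvest_fertility(m[i], x, frac)
        return params.with_rates(fertility=m)
    if kind in ("offtake", "offtake_juvenile", "cat_frequency", "cat_magnitude"):
        return params
    raise ValueError(f"unknown perturbation kind {kind!r}")


def _project_result(params: SpeciesParams, config: SimConfig, perturbation) -> ProjectionResult:
    rng = np.random.default_rng(config.seed)
    base_model = build_leslie(params, census=config.census, g_method=config.g_method)
    if base_model.R0 <= 0:
        raise DemographyError(f"{params.name}: no reproduction, projection is degenerate")
    gen = round_half_up(base_model.G)
    horizon = config.horizon_generations * gen
    burnin = config.burnin_generations * gen

    pparams = _perturbed_params(params, perturbation)
    # the perturbed matrix may be fully degenerate (e.g. survival reduced
    # to 0), so build it without eigenanalysis
    first_row = leslie_matrix(pparams, config.census)[0]

    n0 = initial_population(params, base_model, config.area_km2).n
    if n0.sum() < 1.0:
        raise DemographyError(f"{params.name}: initial population is empty")
    K = params.density * config.area_km2

    c = calibrate_feedback(params, census=config.census) if config.density_feedback_on else 0.0

    # catastrophe regime
    cat_prob_gen = config.cat_prob_per_generation
    severity = config.cat_severity
    freq_mult = np.ones(config.iterations)
    if perturbation is not None:
        if perturbation.kind == "cat_frequency":
            freq_mult[:] = perturbation.intensity
        elif perturbation.kind == "cat_magnitude":
            severity = perturbation.intensity
            hi = perturbation.freq_mult_max
            if hi is None or hi < 1.0:
                hi = 1.0
            freq_mult = rng.uniform(1.0, hi, size=config.iterations)
    cat_prob_year = np.clip(cat_prob_gen * freq_mult / gen, 0.0, 1.0)

    # offtake removal vector (females per year, apportioned by w)
    removal = None
    if perturbation is not None and perturbation.kind in ("offtake", "offtake_juvenile"):
        weights = base_model.w.copy()
        if perturbation.kind == "offtake_juvenile":
            weights[params.alpha :] = 0.0
            tot = weights.sum()
            if tot <= 0:
                raise DemographyError(f"{params.name}: no juvenile classes for offtake")
            weights /= tot
        removal = perturbation.intensity * weights

    stochastic = config.demographic_stochasticity
    if stochastic:
        N = np.tile(np.asarray(np.round(n0), dtype=np.int64), (config.iterations, 1))
    else:
        N = np.tile(n0.astype(float), (config.iterations, 1))

    keep = horizon - burnin
    totals = np.zeros((config.iterations, keep), dtype=float)
    ever_below = np.zeros(config.iterations, dtype=bool)
    threshold = config.eq_threshold_females
    # zero populations are absorbing: stop simulating crashed runs
    alive = np.ones(config.iterations, dtype=bool)

    for t in range(horizon):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            ever_below[:] = True
            break
        Nv = N[idx]
        if removal is not None:
            if stochastic:
                Nv = _apply_offtake(Nv, removal, rng)
            else:
                Nv = np.maximum(Nv - removal[None, :], 0.0)
        tot = Nv.sum(axis=1)
        mult = (
            density_feedback(tot, K, c, config.feedback_theta)
            if (config.density_feedback_on and c > 0)
            else np.ones(idx.size)
        )
        Nv = _step_matrix(Nv, pparams, first_row, np.asarray(mult), rng, stochastic)
        if config.catastrophes_on and stochastic:
            hit = rng.random(idx.size) < cat_prob_year[idx]
            if hit.any():
                Nv[hit] = rng.binomial(Nv[hit], 1.0 - severity)
        N[idx] = Nv
        alive[idx] = Nv.sum(axis=1) > 0
        if t >= burnin:
            totals[alive, t - burnin] = N[alive].sum(axis=1)
            ever_below |= totals[:, t - burnin] < threshold

    finals = totals[:, -1]
    if config.first_passage:
        qe = ever_below
    else:
        qe = finals < threshold
    return ProjectionResult(
        species=params.name,
        finals=finals,
        quasi_extinct=qe,
        pr_eq=float(qe.mean()),
        totals=totals,
        horizon_years=horizon,
        burnin_years=burnin,
    )


def quasi_extinction_probability(
    params: SpeciesParams, config: SimConfig, perturbation=None
) -> float:
    """Pr(final female total < E_q) over the configured ensemble."""
    return _project_result(params, config, perturbation).pr_eq


def deterministic_projection(
    params: SpeciesParams, config: SimConfig, years: int
) -> np.ndarray:
    """Matrix-power sequence of totals (no stochasticity, no feedback,
    no catastrophes); the exact deterministic limit of :func:`project`."""
    model = build_leslie(params, census=config.census, g_method=config.g_method)
    n = initial_population(params, model, config.area_km2).n
    out = np.empty(years + 1)
    out[0] = n.sum()
    for t in range(years):
        n = model.matrix @ n
        out[t + 1] = n.sum()
    return out
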