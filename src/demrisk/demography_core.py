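"""Deterministic pre-breeding Leslie-matrix demography.

Builds female-only, age-classified projection matrices from per-species
demographic rates and derives the standard eigen-quantities: asymptotic
growth rate (lambda), stable age distribution (w), net reproductive rate
(R0), and generation length (G).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SpeciesParams",
    "LeslieModel",
    "PopulationVector",
    "DemographyError",
    "leslie_matrix",
    "build_leslie",
    "stable_structure",
    "generation_length",
    "initial_population",
    "DEFAULT_AREA_KM2",
    "FUNCTIONAL_GROUPS",
    "STATUSES",
]

#: Study-zone surface area (km^2) used to convert density into abundance.
DEFAULT_AREA_KM2 = 250_000.0

FUNCTIONAL_GROUPS = ("vombatiform", "macropodiform", "bird", "carnivore", "monotreme")
STATUSES = ("extinct", "extant")


class DemographyError(ValueError):
    """Raised when demographic inputs or derived quantities are invalid."""


@dataclass(frozen=True)
class SpeciesParams:
    """Complete demographic parameterization of one species.

    Ages run 0..omega inclusive; ``survival`` and ``fertility`` have
    length ``omega + 1``. Fertility is in daughters per female per year.
    ``terminal_self_loop`` controls whether the last age class persists
    (matrix entry ``M[omega, omega] = S_omega``) or is absorbing (0).
    """

    name: str
    status: str
    group: str
    mass_kg: float
    alpha: int
    omega: int
    survival: np.ndarray
    fertility: np.ndarray
    density: float
    terminal_self_loop: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        object.__setattr__(self, "fertility", np.asarray(self.fertility, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.status not in STATUSES:
            raise DemographyError(f"{self.name}: unknown status {self.status!r}")
        if self.group not in FUNCTIONAL_GROUPS:
            raise DemographyError(f"{self.name}: unknown group {self.group!r}")
        if not self.mass_kg > 0:
            raise DemographyError(f"{self.name}: mass_kg must be positive")
        if not (1 <= self.alpha <= self.omega):
            raise DemographyError(
                f"{self.name}: need 1 <= alpha <= omega, got alpha={self.alpha}, omega={self.omega}"
            )
        n = self.omega + 1
        if self.survival.shape != (n,) or self.fertility.shape != (n,):
            raise DemographyError(
                f"{self.name}: survival and fertility must have length omega+1={n}"
            )
        if np.any(self.survival < 0) or np.any(self.survival > 1):
            raise DemographyError(f"{self.name}: survival probabilities outside [0, 1]")
        if np.any(self.fertility < 0):
            raise DemographyError(f"{self.name}: negative fertility")
        if np.any(self.fertility[: self.alpha] != 0):
            raise DemographyError(
                f"{self.name}: fertility must be zero before age at first breeding alpha={self.alpha}"
            )
        if self.density < 0:
            raise DemographyError(f"{self.name}: negative density")

    @property
    def n_ages(self) -> int:
        return self.omega + 1

    def with_rates(
        self,
        survival: np.ndarray | None = None,
        fertility: np.ndarray | None = None,
    ) -> "SpeciesParams":
        """Copy with substituted survival and/or fertility vectors."""
        kwargs = {}
        if survival is not None:
            kwargs["survival"] = np.asarray(survival, dtype=float)
        if fertility is not None:
            kwargs["fertility"] = np.asarray(fertility, dtype=float)
        return replace(self, **kwargs)


@dataclass(frozen=True)
class PopulationVector:
    """Non-negative female abundances by age class."""

    n: np.ndarray = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.n, dtype=float)
        if np.any(arr < 0):
            raise DemographyError("population vector has negative entries")
        object.__setattr__(self, "n", arr)

    @property
    def total(self) -> float:
        return float(self.n.sum())


@dataclass(frozen=True)
class LeslieModel:
    """A Leslie projection matrix with its eigen-derived summaries."""

    matrix: np.ndarray
    lam: float
    w: np.ndarray
    G: float
    R0: float
    params: SpeciesParams

    @property
    def n_ages(self) -> int:
        return self.matrix.shape[0]


def _first_row(params: SpeciesParams, census: str) -> np.ndarray:
    """Fertility row of the projection matrix.

    ``census='pre'`` (default): pre-breeding census, entry j is
    S_j * m_{j+1} — newborns must survive their first year before being
    censused. ``census='post-literal'`` places the raw m_x in row 0.
    """
    s, m, omega = params.survival, params.fertility, params.omega
    if census == "post-literal":
        return m.copy()
    if census != "pre":
        raise DemographyError(f"unknown census convention {census!r}")
    row = np.zeros(omega + 1)
    row[:omega] = s[:omega] * m[1 : omega + 1]
    if params.terminal_self_loop:
        # survivors of the last class remain age omega and breed at m_omega
        row[omega] = s[omega] * m[omega]
    return row


def _dominant_eigenpair(M: np.ndarray, name: str) -> tuple[float, np.ndarray]:
    """Dominant eigenvalue (largest modulus, positive real part) and its
    right eigenvector normalized to sum 1.

    For imprimitive (cyclic) matrices the eigenvector is averaged over one
    power-iteration cycle so it represents the long-run mean structure.
    """
    if not np.any(M):
        raise DemographyError(f"{name}: all-zero projection matrix, eigensolve undefined")
    vals, vecs = np.linalg.eig(M)
    moduli = np.abs(vals)
    lam_mod = moduli.max()
    if lam_mod <= 1e-300:
        # nilpotent chain (no reproduction, absorbing terminal class):
        # spectral radius 0, no meaningful stable structure
        n = M.shape[0]
        return 0.0, np.full(n, 1.0 / n)
    # prefer an (effectively) real, positive eigenvalue at the spectral radius
    at_radius = np.flatnonzero(np.isclose(moduli, lam_mod, rtol=1e-10))
    real_pos = [i for i in at_radius if vals[i].real > 0 and abs(vals[i].imag) <= 1e-9 * lam_mod]
    if real_pos:
        idx = real_pos[0]
        lam = float(vals[idx].real)
        w = np.abs(vecs[:, idx].real)
        if w.sum() == 0:
            w = np.abs(vecs[:, idx])
    else:
        # cyclic case: spectral radius attained only by complex/negative roots;
        # average the age structure over one cycle of power iteration
        lam = float(lam_mod)
        period = max(len(at_radius), 2)
        v = np.ones(M.shape[0])
        for _ in range(500):
            nv = M @ v
            tot = nv.sum()
            if tot == 0:
                raise DemographyError(f"{name}: population annihilated during power iteration")
            v = nv / tot
        acc = np.zeros_like(v)
        for _ in range(period):
            acc += v
            nv = M @ v
            v = nv / nv.sum()
        w = acc / period
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        raise DemographyError(f"{name}: degenerate eigenvector")
    return lam, w / total


def _survivorship(params: SpeciesParams) -> np.ndarray:
    """l_x = probability of surviving from birth to exact age x (l_0 = 1)."""
    l = np.ones(params.omega + 1)
    l[1:] = np.cumprod(params.survival[:-1])
    return l


def _net_fertility(params: SpeciesParams) -> np.ndarray:
    """phi_x = l_x * m_x, the expected daughters produced at age x."""
    return _survivorship(params) * params.fertility


def _r0(params: SpeciesParams) -> float:
    """Net reproductive rate: expected lifetime daughters per newborn female.

    Includes the geometric tail of a terminal self-loop when present.
    """
    phi = _net_fertility(params)
    r0 = float(phi.sum())
    s_om = params.survival[params.omega]
    if params.terminal_self_loop and s_om > 0 and s_om < 1:
        l_om = _survivorship(params)[params.omega]
        # extra years spent in class omega: l_omega * s/(1-s) further breeding years
        r0 += float(l_om * params.fertility[params.omega] * s_om / (1.0 - s_om))
    return r0


def generation_length(
    params: SpeciesParams, lam: float, method: str = "mean_age_mothers"
) -> float:
    """Generation length G in years.

    ``mean_age_mothers`` (default): mean age of the mothers of offspring
    produced at the stable age distribution,
    G = sum(x * lam^-x * l_x * m_x) / sum(lam^-x * l_x * m_x).
    ``log_r0``: G = log(R0) / log(lambda) (undefined at lambda == 1).
    """
    r0 = _r0(params)
    if r0 <= 0:
        raise DemographyError(f"{params.name}: R0 = 0, generation length undefined")
    if method == "log_r0":
        if abs(lam - 1.0) < 1e-12:
            raise DemographyError(
                f"{params.name}: log-ratio generation length undefined at lambda = 1"
            )
        return float(np.log(r0) / np.log(lam))
    if method != "mean_age_mothers":
        raise DemographyError(f"unknown generation-length method {method!r}")
    ages = np.arange(params.omega + 1, dtype=float)
    phi = _net_fertility(params)
    # work in log space: lam**-x overflows for small lam and large omega
    log_phi = np.full_like(phi, -np.inf)
    pos = phi > 0
    log_phi[pos] = np.log(phi[pos])
    log_w = -ages * np.log(lam) + log_phi
    tail = 0.0
    if params.terminal_self_loop and params.survival[params.omega] > 0:
        # breeding continues inside the terminal class; attribute those
        # discounted offspring to age omega so G stays within [alpha, omega]
        ratio = params.survival[params.omega] / lam
        if ratio < 1.0:
            tail = ratio / (1.0 - ratio)  # multiplier on the age-omega weight
    shift = log_w.max()
    w = np.exp(log_w - shift)
    if tail > 0 and w[params.omega] > 0:
        w[params.omega] *= 1.0 + tail
    return float((ages * w).sum() / w.sum())


def leslie_matrix(params: SpeciesParams, census: str = "pre") -> np.ndarray:
    """The bare (omega+1)-square projection matrix, no eigenanalysis.

    Valid even for fully degenerate (all-zero) rate vectors, which the
    stochastic engine must be able to project.
    """
    n = params.n_ages
    M = np.zeros((n, n))
    M[0, :] = _first_row(params, census)
    idx = np.arange(n - 1)
    M[idx + 1, idx] = params.survival[:-1]
    if params.terminal_self_loop:
        M[n - 1, n - 1] = params.survival[-1]
    return M


def build_leslie(
    params: SpeciesParams,
    census: str = "pre",
    g_method: str = "mean_age_mothers",
) -> LeslieModel:
    """Construct the (omega+1)-square female Leslie matrix and its summaries.

    Row 0 holds the (census-adjusted) fertilities, the sub-diagonal holds
    S_0..S_{omega-1}, and the last diagonal entry is S_omega when the
    species keeps a terminal self-loop, otherwise 0.
    """
    M = leslie_matrix(params, census)
    lam, w = _dominant_eigenpair(M, params.name)
    r0 = _r0(params)
    if r0 > 0:
        G = generation_length(params, lam, method=g_method)
    else:
        G = float("nan")
    return LeslieModel(matrix=M, lam=lam, w=w, G=G, R0=r0, params=params)


def stable_structure(model: LeslieModel) -> PopulationVector:
    """Stable age distribution w, scaled to sum to 1."""
    return PopulationVector(model.w.copy())


def initial_population(
    params: SpeciesParams,
    model: LeslieModel,
    area_km2: float = DEFAULT_AREA_KM2,
    project_once: bool = True,
) -> PopulationVector:
    """Starting abundance vector n0 = A * D * (M @ w).

    ``project_once=False`` drops the extra matrix multiplication and
    returns A * D * w instead.
    """
    if not area_km2 > 0:
        raise DemographyError("area_km2 must be positive")
    if params.density == 0:
        warnings.warn(
            f"{params.name}: density is zero, species cannot be simulated",
            stacklevel=2,
        )
        return PopulationVector(np.zeros(params.n_ages))
    base = model.matrix @ model.w if project_once else model.w
    return PopulationVector(area_km2 * params.density * np.clip(base, 0.0, None))
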