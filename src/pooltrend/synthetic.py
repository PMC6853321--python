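"""Synthetic pooled-serum biomonitoring data.

The Australian pooled-serum OCP surveillance design measures organochlorine
pesticide concentrations (ng/g lipid) on pools of individual serum samples,
stratified by age group (5-15, 16-30, 31-45, 46-60, >60 years), gender and
collection period (2002/03 through 2012/13).  Each pool yields a single
concentration that approximates the mean body burden of its stratum.

This module reproduces that design exactly (cell-by-cell pool counts) and
simulates pooled observations from the log-scale generative structure assumed
by the three hierarchical models used downstream:

* model 1 — log-concentration mean is an age-by-time random walk ``beta[a,t]``,
* model 2 — mean is a static age-by-gender level ``alpha[a,g]``,
* model 3 — mean is the sum ``alpha[a,g] + beta[a,t]``.

Observation noise is Normal on the natural-log scale with standard deviation
``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math
from typing import Optional, Sequence

import numpy as np

AGE_GROUPS: tuple[str, ...] = ("5-15", "16-30", "31-45", "46-60", ">60")
GENDERS: tuple[str, ...] = ("male", "female")
PERIODS: tuple[str, ...] = ("2002/03", "2006/07", "2008/09", "2010/11", "2012/13")

#: pool counts of the default design, indexed [age][gender][period]
_DEFAULT_N_POOLS: dict[str, dict[str, tuple[int, ...]]] = {
    "5-15": {"male": (3, 15, 2, 4, 2), "female": (3, 17, 2, 4, 2)},
    "16-30": {"male": (3, 2, 2, 4, 2), "female": (3, 2, 2, 4, 2)},
    "31-45": {"male": (1, 2, 2, 4, 2), "female": (1, 2, 2, 4, 2)},
    "46-60": {"male": (3, 2, 2, 4, 2), "female": (3, 2, 2, 4, 2)},
    ">60": {"male": (3, 2, 2, 4, 2), "female": (3, 2, 2, 4, 2)},
}

#: pools collected in 2006/07 were smaller (up to 30 individuals); all other
#: periods pooled 100 individual samples
_DEFAULT_POOL_SIZE = {p: (30 if p == "2006/07" else 100) for p in PERIODS}


class ValidationError(ValueError):
    """Raised when inputs violate the design or model contracts."""


@dataclass(frozen=True)
class DesignCell:
    """One stratum of the pooled design: how many pools of what size."""

    age_group: str
    gender: str
    period: str
    n_pools: int
    pool_size: int

    def __post_init__(self) -> None:
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"unknown age group {self.age_group!r}")
        if self.gender not in GENDERS:
            raise ValidationError(f"unknown gender {self.gender!r}")
        if self.period not in PERIODS:
            raise ValidationError(f"unknown period {self.period!r}")
        if self.n_pools < 0:
            raise ValidationError("n_pools must be >= 0")
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")

    @property
    def t(self) -> int:
        """1-based time index of the collection period."""
        return PERIODS.index(self.period) + 1


@dataclass(frozen=True)
class PooledObservation:
    """A single pooled measurement with its design cell.

    ``concentration`` is on the natural scale (ng/g lipid);
    ``log_concentration`` is its natural logarithm, the response modelled
    throughout.
    """

    ocp: str
    age_group: str
    gender: str
    period: str
    concentration: float
    log_concentration: float
    pool_size: int

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if not math.isclose(
            self.log_concentration, math.log(self.concentration), rel_tol=1e-12, abs_tol=1e-12
        ):
            raise ValidationError("log_concentration != ln(concentration)")
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")

    @classmethod
    def from_log(
        cls, ocp: str, age_group: str, gender: str, period: str, log_concentration: float, pool_size: int
    ) -> "PooledObservation":
        return cls(
            ocp=ocp,
            age_group=age_group,
            gender=gender,
            period=period,
            concentration=math.exp(log_concentration),
            log_concentration=log_concentration,
            pool_size=pool_size,
        )


@dataclass
class GenerativeParams:
    """True parameter set for one of the three generative models.

    Parameters
    ----------
    model_spec : {1, 2, 3}
        Which mean structure to simulate from.
    beta_a0 : array_like of shape (5,), optional
        Per-age initial log-level of the random walk (models 1 and 3).
    omega : float, optional
        Random-walk innovation standard deviation (models 1 and 3).
    sigma : float
        Observation standard deviation on the log scale.
    alpha_ag : array_like of shape (5, 2), optional
        Age-by-gender levels (models 2 and 3).
    beta_at : array_like of shape (5, 5), optional
        If given, a fully specified age-by-time surface used verbatim instead
        of drawing the random walk — useful for planting exact interaction
        patterns in simulation studies.
    alpha_g, delta_a, delta_g, phi
        Group-level means/scales; recorded for completeness (they parameterise
        the fitted models' priors) but not needed to simulate once
        ``alpha_ag`` is fixed.
    """

    model_spec: int
    sigma: float = 0.5
    omega: Optional[float] = None
    beta_a0: Optional[np.ndarray] = None
    alpha_ag: Optional[np.ndarray] = None
    beta_at: Optional[np.ndarray] = None
    alpha_g: Optional[np.ndarray] = None
    delta_a: Optional[np.ndarray] = None
    delta_g: Optional[np.ndarray] = None
    phi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.model_spec not in (1, 2, 3):
            raise ValidationError(f"model_spec must be 1, 2 or 3, got {self.model_spec}")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")
        if self.omega is not None and self.omega < 0:
            raise ValidationError("omega must be >= 0")
        if self.phi is not None and self.phi < 0:
            raise ValidationError("phi must be >= 0")
        for name in ("beta_a0", "alpha_ag", "beta_at", "alpha_g", "delta_a", "delta_g"):
            v = getattr(self, name)
            if v is not None:
                object.__setattr__(self, name, np.asarray(v, dtype=float))
        if self.model_spec in (1, 3):
            if self.beta_at is None and (self.beta_a0 is None or self.omega is None):
                raise ValidationError(
                    f"model {self.model_spec} needs beta_a0 and omega (or an explicit beta_at)"
                )
        if self.model_spec in (2, 3):
            if self.alpha_ag is None:
                raise ValidationError(f"model {self.model_spec} needs alpha_ag")


def example_params(model_spec: int) -> GenerativeParams:
    """Study-realistic default parameters for simulation experiments.

    Log levels rise with age (older cohorts lived through the agricultural
    use of OCPs and carry a larger accumulated burden), women run slightly
    higher than men, and the scales sit in the range typical of pooled-serum
    log-concentration data (sigma ~ 0.3-0.8).
    """
    beta_a0 = np.array([3.0, 3.4, 3.8, 4.2, 4.6])
    alpha_ag = np.column_stack([beta_a0 - 0.15, beta_a0 + 0.15])  # women higher
    if model_spec == 1:
        return GenerativeParams(1, sigma=0.5, omega=0.2, beta_a0=beta_a0)
    if model_spec == 2:
        return GenerativeParams(2, sigma=0.5, alpha_ag=alpha_ag)
    if model_spec == 3:
        return GenerativeParams(
            3,
            sigma=0.5,
            omega=0.2,
            beta_a0=np.zeros(5) + np.array([-0.4, -0.2, 0.0, 0.2, 0.4]),
            alpha_ag=alpha_ag,
        )
    raise ValidationError(f"model_spec must be 1, 2 or 3, got {model_spec}")


def study_like_params() -> GenerativeParams:
    """A fully planted model-3 truth emulating the observed study regime.

    Concentrations decline over the decade in every age group with
    non-parallel, age-specific slopes (an age-by-time interaction), and women
    run higher than men with the gap widening in the older groups (an
    age-by-gender interaction).  The temporal surface is given explicitly
    (``beta_at``) rather than drawn, so simulation studies built on it vary
    only through observation noise.
    """
    base = np.array([3.0, 3.4, 3.8, 4.2, 4.6])
    slopes = np.array([-0.05, -0.08, -0.11, -0.14, -0.17])  # log units per period
    beta_at = slopes[:, None] * np.arange(5)[None, :]
    gender_gap = np.array([0.1, 0.1, 0.2, 0.4, 0.4])  # women minus men
    alpha_ag = np.column_stack([base - gender_gap / 2, base + gender_gap / 2])
    return GenerativeParams(3, sigma=0.4, beta_at=beta_at, alpha_ag=alpha_ag)


def default_design() -> list[DesignCell]:
    """The printed study design: 50 cells, 154 pools, unbalanced.

    Pool counts match the published per-cell table; 2006/07 pools hold 30
    individuals, all other periods 100.  The 0-4 age group (absent in
    2002/03) is excluded.
    """
    cells = []
    for age in AGE_GROUPS:
        for gender in GENDERS:
            for j, period in enumerate(PERIODS):
                cells.append(
                    DesignCell(
                        age_group=age,
                        gender=gender,
                        period=period,
                        n_pools=_DEFAULT_N_POOLS[age][gender][j],
                        pool_size=_DEFAULT_POOL_SIZE[period],
                    )
                )
    return cells


def make_design(n_pools_per_cell: int, pool_size: int) -> list[DesignCell]:
    """A balanced 50-cell design for simulation studies."""
    if n_pools_per_cell < 0:
        raise ValidationError("n_pools_per_cell must be >= 0")
    if pool_size < 1:
        raise ValidationError("pool_size must be >= 1")
    return [
        DesignCell(age_group=a, gender=g, period=p, n_pools=n_pools_per_cell, pool_size=pool_size)
        for a in AGE_GROUPS
        for g in GENDERS
        for p in PERIODS
    ]


def _cell_mean_surface(params: GenerativeParams, rng: np.random.Generator) -> np.ndarray:
    """Realize the (age, gender, period) grid of true log-scale means."""
    A, G, T = len(AGE_GROUPS), len(GENDERS), len(PERIODS)
    if params.model_spec in (1, 3):
        if params.beta_at is not None:
            beta = np.asarray(params.beta_at, dtype=float)
            if beta.shape != (A, T):
                raise ValidationError(f"beta_at must have shape {(A, T)}")
        else:
            beta = np.empty((A, T))
            prev = np.asarray(params.beta_a0, dtype=float)
            if prev.shape != (A,):
                raise ValidationError(f"beta_a0 must have shape {(A,)}")
            for t in range(T):
                prev = rng.normal(prev, params.omega)
                beta[:, t] = prev
    if params.model_spec == 1:
        return np.broadcast_to(beta[:, None, :], (A, G, T)).copy()
    alpha = np.asarray(params.alpha_ag, dtype=float)
    if alpha.shape != (A, G):
        raise ValidationError(f"alpha_ag must have shape {(A, G)}")
    if params.model_spec == 2:
        return np.broadcast_to(alpha[:, :, None], (A, G, T)).copy()
    return alpha[:, :, None] + beta[:, None, :]


def simulate_with_truth(
    design: Sequence[DesignCell],
    params: GenerativeParams,
    seed: int,
    ocp: str = "HCB",
    sigma_scales_with_pool_size: bool = False,
) -> tuple[list[PooledObservation], dict]:
    """Simulate pooled observations and return the realized truth.

    Returns ``(observations, truth)`` where ``truth['cell_means']`` is the
    realized (5, 2, 5) grid of true log-scale cell means (including any
    random-walk draw) and ``truth['params']`` echoes the input.  Identical
    ``(design, params, seed)`` triples yield identical output.
    """
    ss = np.random.SeedSequence(seed)
    rng_walk, rng_obs = (np.random.default_rng(s) for s in ss.spawn(2))
    means = _cell_mean_surface(params, rng_walk)
    obs: list[PooledObservation] = []
    for cell in design:
        a = AGE_GROUPS.index(cell.age_group)
        g = GENDERS.index(cell.gender)
        t = PERIODS.index(cell.period)
        sd = params.sigma
        if sigma_scales_with_pool_size:
            sd = sd / math.sqrt(cell.pool_size)
        logs = rng_obs.normal(means[a, g, t], sd, size=cell.n_pools)
        for v in logs:
            obs.append(
                PooledObservation.from_log(ocp, cell.age_group, cell.gender, cell.period, float(v), cell.pool_size)
            )
    truth = {"cell_means": means, "params": params}
    return obs, truth


def simulate_dataset(
    design: Sequence[DesignCell],
    params: GenerativeParams,
    seed: int,
    ocp: str = "HCB",
    sigma_scales_with_pool_size: bool = False,
) -> list[PooledObservation]:
    """Simulate one pooled dataset (one observation per pool in the design)."""
    obs, _ = simulate_with_truth(design, params, seed, ocp, sigma_scales_with_pool_size)
    return obs
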