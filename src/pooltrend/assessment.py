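"""Model assessment: predictive-interval coverage, DIC and RMSE.

For a fitted hierarchical model this module computes the standard adequacy
summaries for pooled log-concentration data:

* **PI coverage** — the percentage of observations falling inside their own
  central posterior-predictive intervals at nominal levels 80/90/95%;
* **DIC** — the deviance information criterion ``D(theta*) + 2 pD`` with
  effective parameter count ``pD = Dbar - D(theta*)``, where ``theta*`` is
  the posterior mean vector and the deviance conditions on the lowest-level
  parameters (conditional DIC);
* **RMSE** — root mean squared error of the posterior-mean fitted values on
  the log scale;
* the posterior mean of the observation SD ``sigma`` with a 95% credible
  interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .models import ModelDefinition, PosteriorDraws
from .synthetic import PooledObservation, ValidationError

_LOG_2PI = float(np.log(2.0 * np.pi))


def _fitted_mean_matrix(
    draws: PosteriorDraws, model: ModelDefinition, data: Sequence[PooledObservation]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-draw fitted mean for each observation.

    Returns ``(M, sigma, y)`` with ``M`` of shape (n_draws, n_obs).
    """
    idx, y = model.encode(data)
    mat = draws.stacked()
    cells = model.cell_means(mat)  # (N, A, G, T)
    M = cells[:, idx[:, 0], idx[:, 1], idx[:, 2]]
    sigma = mat[:, draws.param_names.index("sigma")]
    return M, sigma, y


def _minus2_loglik(M: np.ndarray, sigma: np.ndarray, y: np.ndarray) -> np.ndarray:
    """-2 log-likelihood per draw (vectorized over the draw axis)."""
    nobs = len(y)
    sse = ((y[None, :] - M) ** 2).sum(axis=1)
    return nobs * (_LOG_2PI + 2.0 * np.log(sigma)) + sse / sigma**2


def pi_coverage(
    draws: PosteriorDraws,
    model: ModelDefinition,
    data: Sequence[PooledObservation],
    alpha: float,
    seed: int = 0,
) -> float:
    """Observed coverage (%) of the central (1-alpha) predictive intervals.

    Each observation's posterior-predictive sample adds fresh Normal(0,
    sigma-draw) observation noise to its per-draw fitted mean; the empirical
    central interval is compared with the observed value.
    """
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    M, sigma, y = _fitted_mean_matrix(draws, model, data)
    rng = np.random.default_rng(np.random.SeedSequence((draws.seed, seed)))
    pred = M + sigma[:, None] * rng.standard_normal(M.shape)
    lo, hi = np.quantile(pred, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0)
    inside = (y >= lo) & (y <= hi)
    return float(100.0 * inside.mean())


class DicResult(NamedTuple):
    dic: float
    p_d: float
    d_bar: float
    d_at_mean: float


def dic(
    draws: PosteriorDraws, model: ModelDefinition, data: Sequence[PooledObservation]
) -> DicResult:
    """Deviance information criterion and its components.

    ``d_bar`` is the posterior mean of the deviance (-2 log-likelihood),
    ``d_at_mean`` the deviance at the posterior mean parameter vector
    (including sigma), ``p_d = d_bar - d_at_mean`` and
    ``dic = d_at_mean + 2 p_d``.
    """
    if draws.draws.size == 0:
        raise ValidationError("empty draws")
    M, sigma, y = _fitted_mean_matrix(draws, model, data)
    d_bar = float(_minus2_loglik(M, sigma, y).mean())
    theta_star = draws.stacked().mean(axis=0)
    idx, _ = model.encode(data)
    m_star = model.cell_means(theta_star)[0][idx[:, 0], idx[:, 1], idx[:, 2]]
    s_star = float(theta_star[draws.param_names.index("sigma")])
    d_at_mean = float(_minus2_loglik(m_star[None, :], np.array([s_star]), y)[0])
    p_d = d_bar - d_at_mean
    return DicResult(dic=d_at_mean + 2.0 * p_d, p_d=p_d, d_bar=d_bar, d_at_mean=d_at_mean)


def model_rmse(
    draws: PosteriorDraws, model: ModelDefinition, data: Sequence[PooledObservation]
) -> float:
    """RMSE of posterior-mean fitted values against observed log values."""
    M, _, y = _fitted_mean_matrix(draws, model, data)
    if len(y) == 0:
        raise ValidationError("empty data")
    yhat = M.mean(axis=0)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass
class AssessmentReport:
    """One row of the model-diagnostics table for a single model/OCP."""

    model_spec: int
    pi_coverage: dict[int, float]  # nominal percent level -> observed %
    dic: float
    p_d: float
    d_bar: float
    d_at_mean: float
    rmse: float
    sigma_mean: float
    sigma_ci: tuple[float, float]

    def to_row(self) -> dict:
        return {
            "model": self.model_spec,
            "pi_80": self.pi_coverage.get(80),
            "pi_90": self.pi_coverage.get(90),
            "pi_95": self.pi_coverage.get(95),
            "dic": self.dic,
            "p_d": self.p_d,
            "rmse": self.rmse,
            "sigma_post_mean": self.sigma_mean,
            "sigma_ci_low": self.sigma_ci[0],
            "sigma_ci_high": self.sigma_ci[1],
        }


def assess(
    draws: PosteriorDraws,
    model: ModelDefinition,
    data: Sequence[PooledObservation],
    levels: Sequence[float] = (0.2, 0.1, 0.05),
    seed: int = 0,
) -> AssessmentReport:
    """Full diagnostics row: PI coverages, DIC with pD, RMSE, sigma summary."""
    cov = {
        int(round(100 * (1 - a))): pi_coverage(draws, model, data, a, seed=seed) for a in levels
    }
    d = dic(draws, model, data)
    sig = draws.get("sigma").ravel()
    lo, hi = np.quantile(sig, [0.025, 0.975])
    return AssessmentReport(
        model_spec=model.spec,
        pi_coverage=cov,
        dic=d.dic,
        p_d=d.p_d,
        d_bar=d.d_bar,
        d_at_mean=d.d_at_mean,
        rmse=model_rmse(draws, model, data),
        sigma_mean=float(sig.mean()),
        sigma_ci=(float(lo), float(hi)),
    )


def compare_models(reports: Sequence[AssessmentReport]) -> pd.DataFrame:
    """Rank fitted models by DIC (ties shared, never broken silently).

    RMSE and the distance of each PI coverage from its nominal level are
    reported alongside; no single aggregate score is formed.
    """
    if len(reports) < 2:
        raise ValidationError("need at least 2 reports to compare")
    rows = []
    for r in reports:
        row = r.to_row()
        for lv in (80, 90, 95):
            c = r.pi_coverage.get(lv)
            row[f"pi_{lv}_abs_dev"] = abs(c - lv) if c is not None else None
        rows.append(row)
    df = pd.DataFrame(rows)
    df["dic_rank"] = df["dic"].rank(method="min").astype(int)
    df["dic_tied"] = df.duplicated("dic", keep=False)
    return df.sort_values("dic_rank").reset_index(drop=True)
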