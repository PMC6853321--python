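"""Posterior trend and change inference.

Turns posterior draws into the study's third-stage summaries: fitted
log-concentration trajectories per design cell with 95% credible bands,
percent change between collection periods (overall, consecutive, and the
cohort extrapolation that follows an age band as it moves into the adjacent
older band over the decade), and the subsampling sensitivity assessment for
the oversampled 5-15 / 2006/07 cell.

Percent changes are computed draw-wise on the natural concentration scale,
``100 * (exp(m_to) - exp(m_from)) / exp(m_from)``, then summarized by the
posterior mean and central 95% interval, so the credible interval is a true
interval of the percent change itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import ModelDefinition, PosteriorDraws, build_model, sample_posterior
from .synthetic import GENDERS, PooledObservation, ValidationError


class TimeNotInModelError(ValueError):
    """Temporal change requested from a model whose mean has no time term.

    Model 2 describes concentrations by age-gender differences only; OCPs
    fitted by it are excluded from between-period change analyses.
    """


def _cell_mean_draws(draws: PosteriorDraws, model: ModelDefinition) -> np.ndarray:
    """(n_draws, A, G, T) mean-function evaluations."""
    return model.cell_means(draws.stacked())


def trajectories(draws: PosteriorDraws, model: ModelDefinition) -> pd.DataFrame:
    """Posterior mean and 95% credible interval of each cell's fitted mean.

    Returns a tidy frame with one row per (age_group, gender, period); for
    model 1 (no gender in the mean) both genders carry identical values.
    """
    cm = _cell_mean_draws(draws, model)
    mean = cm.mean(axis=0)
    lo, hi = np.quantile(cm, [0.025, 0.975], axis=0)
    rows = []
    for i, a in enumerate(model.age_groups):
        for j, g in enumerate(model.genders):
            for k, p in enumerate(model.periods):
                rows.append(
                    {
                        "age_group": a,
                        "gender": g,
                        "period": p,
                        "post_mean": mean[i, j, k],
                        "ci_low": lo[i, j, k],
                        "ci_high": hi[i, j, k],
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChangeSummary:
    """Percent change between two design-grid endpoints."""

    age_group: str
    comparison: tuple[str, str]  # labelled endpoints (period or age@period)
    percent_change: float
    ci_low: float
    ci_high: float


def _require_time(model: ModelDefinition) -> None:
    if not model.has_time:
        raise TimeNotInModelError(
            f"model {model.spec} has no temporal term in its mean; "
            "between-period change is undefined (OCPs fitted by this model "
            "are excluded from change analyses)"
        )


def change_draws(
    draws: PosteriorDraws,
    model: ModelDefinition,
    age_from: str,
    period_from: str,
    age_to: str,
    period_to: str,
    gender: Optional[str] = None,
) -> np.ndarray:
    """Draw-wise percent change between two grid cells.

    For model 1 the mean has no gender term, so ``gender`` is irrelevant;
    for model 3 the change is gender-invariant whenever ``age_from ==
    age_to`` (alpha cancels in the ratio) and a gender must be named for
    cross-age comparisons (default: average the two genders' cell means on
    the log scale).
    """
    _require_time(model)
    cm = _cell_mean_draws(draws, model)
    ia_f, ia_t = model.age_groups.index(age_from), model.age_groups.index(age_to)
    ip_f, ip_t = model.periods.index(period_from), model.periods.index(period_to)
    if gender is None:
        m_from = cm[:, ia_f, :, ip_f].mean(axis=1)
        m_to = cm[:, ia_t, :, ip_t].mean(axis=1)
    else:
        ig = model.genders.index(gender)
        m_from = cm[:, ia_f, ig, ip_f]
        m_to = cm[:, ia_t, ig, ip_t]
    return 100.0 * np.expm1(m_to - m_from)


def _summarize(pct: np.ndarray, age_group: str, comparison: tuple[str, str]) -> ChangeSummary:
    lo, hi = np.quantile(pct, [0.025, 0.975])
    return ChangeSummary(
        age_group=age_group,
        comparison=comparison,
        percent_change=float(pct.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
    )


def percent_change(
    draws: PosteriorDraws,
    model: ModelDefinition,
    age_group: str,
    from_period: str,
    to_period: str,
    gender: Optional[str] = None,
) -> ChangeSummary:
    """Percent change of one age group's concentration between two periods."""
    pct = change_draws(draws, model, age_group, from_period, age_group, to_period, gender)
    return _summarize(pct, age_group, (from_period, to_period))


def consecutive_changes(draws: PosteriorDraws, model: ModelDefinition) -> list[ChangeSummary]:
    """Percent change between each adjacent pair of collection periods.

    One summary per (age group, adjacent period pair), ordered by age group
    then chronologically.
    """
    _require_time(model)
    out = []
    for a in model.age_groups:
        for p_from, p_to in zip(model.periods[:-1], model.periods[1:]):
            out.append(percent_change(draws, model, a, p_from, p_to))
    return out


def cohort_changes(
    draws: PosteriorDraws, model: ModelDefinition, gender: Optional[str] = None
) -> list[ChangeSummary]:
    """Cohort extrapolation: first-period age band vs the adjacent older band
    at the last period.

    Tracks each birth cohort over the study decade: age band ``a`` at the
    first collection period is compared with band ``a+1`` at the last, giving
    one fewer summaries than there are age bands.
    """
    _require_time(model)
    p_first, p_last = model.periods[0], model.periods[-1]
    out = []
    for a_from, a_to in zip(model.age_groups[:-1], model.age_groups[1:]):
        pct = change_draws(draws, model, a_from, p_first, a_to, p_last, gender)
        out.append(
            _summarize(pct, a_from, (f"{a_from}@{p_first}", f"{a_to}@{p_last}"))
        )
    return out


def changes_to_frame(changes: Sequence[ChangeSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age_group": [c.age_group for c in changes],
            "from": [c.comparison[0] for c in changes],
            "to": [c.comparison[1] for c in changes],
            "percent_change": [c.percent_change for c in changes],
            "ci_low": [c.ci_low for c in changes],
            "ci_high": [c.ci_high for c in changes],
        }
    )


def subsample_cell(
    data: Sequence[PooledObservation],
    target_age: str = "5-15",
    target_period: str = "2006/07",
    n_keep_per_gender: int = 4,
    seed: int = 0,
) -> list[PooledObservation]:
    """Randomly thin one design cell to ``n_keep_per_gender`` pools per gender."""
    rng = np.random.default_rng(seed)
    kept: list[PooledObservation] = []
    for gender in GENDERS:
        cell_idx = [
            i
            for i, o in enumerate(data)
            if o.age_group == target_age and o.period == target_period and o.gender == gender
        ]
        if len(cell_idx) < n_keep_per_gender:
            raise ValidationError(
                f"cell ({target_age}, {gender}, {target_period}) has "
                f"{len(cell_idx)} pools < n_keep_per_gender={n_keep_per_gender}"
            )
        keep = set(rng.choice(cell_idx, size=n_keep_per_gender, replace=False).tolist())
        kept.extend(i for i in cell_idx if i in keep)
    other = [
        i
        for i, o in enumerate(data)
        if not (o.age_group == target_age and o.period == target_period)
    ]
    sel = sorted(other + kept)
    return [data[i] for i in sel]


def sensitivity_subsample(
    data: Sequence[PooledObservation],
    target_age: str = "5-15",
    target_period: str = "2006/07",
    n_keep_per_gender: int = 4,
    seed: int = 0,
    n_chains: int = 2,
    n_iter: int = 2000,
    n_burnin: int = 2000,
) -> tuple[list[PooledObservation], pd.DataFrame]:
    """Subsampling sensitivity assessment of the oversampled cell.

    Randomly retains ``n_keep_per_gender`` pools per gender in the target
    cell, refits all three models on the full and reduced datasets, and
    returns the reduced data together with paired posterior summaries of the
    target cell's fitted mean under each model (beta[a,t] for model 1,
    alpha[a,g] for model 2, alpha + beta for model 3).
    """
    reduced = subsample_cell(data, target_age, target_period, n_keep_per_gender, seed)
    rows = []
    for spec in (1, 2, 3):
        model = build_model(spec)
        ia = model.age_groups.index(target_age)
        ip = model.periods.index(target_period)
        for label, d in (("full", data), ("subsampled", reduced)):
            draws = sample_posterior(
                model, d, n_chains=n_chains, n_iter=n_iter, n_burnin=n_burnin, seed=seed
            )
            cm = _cell_mean_draws(draws, model)
            for ig, g in enumerate(model.genders):
                cell = cm[:, ia, ig, ip]
                rows.append(
                    {
                        "model": spec,
                        "dataset": label,
                        "gender": g,
                        "post_mean": float(cell.mean()),
                        "post_sd": float(cell.std(ddof=1)),
                    }
                )
    return reduced, pd.DataFrame(rows)
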