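"""Quartile expression grouping, Kaplan-Meier / log-rank / Cox screening.

Patients strictly above the 75th expression percentile form the high group
and those strictly below the 25th percentile the low group; the middle 50%
are excluded (an ``upper_quartile`` scheme splitting at Q3 alone is
available). High vs. low groups are compared with the two-group log-rank
test and a univariate Cox proportional-hazards fit; a gene is flagged a
death-risk indicator when the log-rank p is below 0.05 *and* the hazard
ratio is at least 1.

Estimation is delegated to lifelines (product-limit KM, chi-square log-rank
with 1 df, Cox partial likelihood with Efron tie handling — equivalent to
Breslow in the tie-free continuous-time cohorts this package generates).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .core import (
    DegenerateGroupingError,
    InvalidParameterError,
    NonConvergenceError,
    SurvivalCohort,
)

QUARTILE_SCHEMES = ("extremes", "upper_quartile")


def quartile_groups(
    expression: pd.Series, scheme: str = "extremes"
) -> pd.Series:
    """Assign each patient to {high, low, excluded} by expression quartile.

    Percentiles use linear interpolation between order statistics. With the
    default ``extremes`` scheme, high = strictly above Q3 and low = strictly
    below Q1; with ``upper_quartile``, low is everyone not above Q3. The
    grouping depends only on ranks, so it is invariant under strictly
    monotone transforms.
    """
    if scheme not in QUARTILE_SCHEMES:
        raise InvalidParameterError(f"unknown quartile scheme {scheme!r}")
    values = expression.to_numpy(float)
    if len(values) < 8:
        raise InvalidParameterError("at least 8 patients are required")
    q1, q3 = np.percentile(values, [25, 75])
    if q1 == q3:
        raise DegenerateGroupingError(
            "expression quartiles coincide; grouping is degenerate"
        )
    out = pd.Series("excluded", index=expression.index, name="group")
    out[values > q3] = "high"
    if scheme == "extremes":
        out[values < q1] = "low"
    else:
        out[values <= q3] = "low"
    return out


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate as a right-continuous step function.

    Returns a frame with columns ``time`` and ``survival`` (the estimate
    just after each observed time); deaths are processed before censorings
    at tied times.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.size == 0:
        raise InvalidParameterError("empty cohort")
    if (times < 0).any():
        raise InvalidParameterError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(float), "survival": sf.iloc[:, 0].to_numpy(float)}
    )


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Two-group log-rank statistic (chi-square, 1 df) and p-value."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    if times_a.size == 0 or times_b.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if events_a.sum() + events_b.sum() == 0:
        raise InvalidParameterError("log-rank test requires at least one event")
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_hr(
    times, events, group
) -> tuple[float, tuple[float, float], float]:
    """Univariate Cox fit on a binary group covariate (1 = high).

    Returns (hazard ratio, 95% CI, Wald p). Raises on a single covariate
    level, fewer than two events, or a monotone (separated) likelihood.
    """
    frame = pd.DataFrame(
        {
            "time": np.asarray(times, float),
            "event": np.asarray(events, int),
            "group": np.asarray(group, int),
        }
    )
    if frame["group"].nunique() < 2:
        raise InvalidParameterError("group covariate has a single level")
    if frame["event"].sum() < 2:
        raise InvalidParameterError("Cox fit requires at least two events")
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="time", event_col="event")
    except ConvergenceError as err:
        raise NonConvergenceError(
            f"Cox partial likelihood did not converge (possible complete "
            f"separation of event order): {err}"
        ) from err
    beta = float(cph.params_["group"])
    se = float(cph.standard_errors_["group"])
    hr = float(np.exp(beta))
    ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
    p = float(cph.summary.loc["group", "p"])
    return hr, ci, p


@dataclass(frozen=True)
class GeneSurvivalResult:
    """Per-gene screening outcome; ``status`` is "ok" or a skip reason."""

    gene: str
    n_high: int
    n_low: int
    logrank_p: float
    hr: float
    ci_low: float
    ci_high: float
    risk_flag: bool
    status: str = "ok"


def screen_genes(
    cohort: SurvivalCohort,
    genes=None,
    alpha: float = 0.05,
    scheme: str = "extremes",
) -> pd.DataFrame:
    """Quartile-split, log-rank and Cox screen for every gene.

    risk_flag is True iff logrank_p < alpha and HR >= 1. Genes whose
    grouping or fit fails are reported with a status message rather than
    dropped.
    """
    genes = list(genes) if genes is not None else cohort.genes
    rows = []
    for gene in genes:
        try:
            if gene not in cohort.genes:
                raise InvalidParameterError("gene absent from cohort")
            grp = quartile_groups(cohort.expression(gene), scheme=scheme)
            sel = grp.isin(["high", "low"])
            sub = cohort.data.loc[sel]
            is_high = (grp[sel] == "high").to_numpy()
            stat, p = logrank_test(
                sub.loc[is_high, "time"], sub.loc[is_high, "event"],
                sub.loc[~is_high, "time"], sub.loc[~is_high, "event"],
            )
            hr, (lo, hi), _ = cox_hr(sub["time"], sub["event"], is_high.astype(int))
            rows.append(GeneSurvivalResult(
                gene=gene, n_high=int(is_high.sum()), n_low=int((~is_high).sum()),
                logrank_p=p, hr=hr, ci_low=lo, ci_high=hi,
                risk_flag=bool(p < alpha and hr >= 1.0),
            ))
        except (InvalidParameterError, DegenerateGroupingError, NonConvergenceError) as err:
            rows.append(GeneSurvivalResult(
                gene=gene, n_high=0, n_low=0, logrank_p=float("nan"),
                hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                risk_flag=False, status=f"skipped: {err}",
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def plot_km(cohort: SurvivalCohort, gene: str, ax=None, scheme: str = "extremes"):
    """Basic two-group Kaplan-Meier figure for one gene (high vs. low)."""
    import matplotlib.pyplot as plt

    grp = quartile_groups(cohort.expression(gene), scheme=scheme)
    if ax is None:
        _, ax = plt.subplots()
    for label in ("high", "low"):
        sel = grp == label
        kmf = KaplanMeierFitter()
        kmf.fit(cohort.data.loc[sel, "time"], cohort.data.loc[sel, "event"], label=label)
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_title(gene)
    return ax
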