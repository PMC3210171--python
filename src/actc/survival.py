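"""Survival statistics for classifier training and evaluation.

Patients are dichotomized on an object-count cut-off (the cohort median
during training, fixed cut-offs 1-10 for reporting) and the two groups are
compared by a Cox proportional-hazards model with a single binary covariate
(Efron correction for ties) and by Kaplan-Meier curves.  A linear regression
between automated and manual counts converts the routine manual cut-off into
an automated-count cut-off.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats


@dataclass(frozen=True)
class SurvivalSummary:
    """Two-group comparison: hazard ratio with 95% CI, median OS per group.

    ``hr`` is the hazard of the high-count group (count >= cutoff) relative
    to the low-count group.  Medians are ``nan`` when the survival curve
    never reaches 0.5 ("not reached").  ``converged`` is False for monotone
    partial likelihoods (all events in one group) — the point estimate is
    then not meaningful and must not be used silently.
    """

    hr: float
    ci_low: float
    ci_high: float
    median_os_low_group: float
    median_os_high_group: float
    n_high: int
    n_low: int
    n_events: int
    converged: bool = True


def _as_arrays(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("need at least one subject")
    if (t <= 0).any():
        raise ValueError("survival times must be strictly positive")
    if not np.isin(e, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")
    return t, e


def km_curve(times, events) -> KaplanMeierFitter:
    """Product-limit (Kaplan-Meier) estimate of the survival function."""
    t, e = _as_arrays(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    return kmf


def km_median(times, events) -> float:
    """Median overall survival; ``nan`` if the curve never reaches 0.5."""
    med = km_curve(times, events).median_survival_time_
    return float("nan") if math.isinf(med) else float(med)


def _breslow_fit(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Newton maximization of the Breslow partial likelihood for one binary
    covariate; returns (beta_hat, se).  Tied event times share the full risk
    set (the Breslow convention)."""
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order], g[order].astype(float)
    first = np.searchsorted(t, t, side="left")  # risk set = {j : t_j >= t_i}

    def derivatives(beta: float) -> tuple[float, float]:
        w = np.exp(beta * g)
        s0 = np.cumsum(w[::-1])[::-1][first]
        s1 = np.cumsum((g * w)[::-1])[::-1][first]
        p = s1 / s0
        grad = float(np.sum(e * (g - p)))
        hess = -float(np.sum(e * p * (1.0 - p)))  # g binary => S2 == S1
        return grad, hess

    beta = 0.0
    hess = -1.0
    for _ in range(100):
        grad, hess = derivatives(beta)
        if hess >= 0:
            break
        step = -grad / hess
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < 1e-12:
            break
    se = math.sqrt(-1.0 / hess) if hess < 0 else float("nan")
    return beta, se


def _efron_fit(t: np.ndarray, e: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """Newton maximization of the Efron-corrected partial likelihood for one
    binary covariate; returns (beta_hat, se).  Vectorized over tie groups, so
    it is fast enough to sit inside the classifier grid search."""
    order = np.argsort(t, kind="stable")
    t, e, g = t[order], e[order].astype(bool), g[order].astype(float)
    first = np.searchsorted(t, t, side="left")  # risk-set start per subject

    te = t[e]
    ge = g[e]
    first_e = np.searchsorted(te, te, side="left")
    d = np.searchsorted(te, te, side="right") - first_e  # tie-group size
    frac = (np.arange(te.size) - first_e) / d  # j/d within each tie group
    starts = np.unique(first_e)
    gid = np.searchsorted(starts, first_e)
    risk_at = first[np.flatnonzero(e)]  # risk-set index per event

    def derivatives(beta: float) -> tuple[float, float]:
        w = np.exp(beta * g)
        suf_w = np.cumsum(w[::-1])[::-1]
        suf_gw = np.cumsum((g * w)[::-1])[::-1]
        s0 = suf_w[risk_at]
        s1 = suf_gw[risk_at]
        we = w[e]
        t0 = np.add.reduceat(we, starts)[gid]
        t1 = np.add.reduceat(ge * we, starts)[gid]
        denom = s0 - frac * t0
        p = (s1 - frac * t1) / denom
        grad = float(np.sum(ge - p))
        hess = -float(np.sum(p * (1.0 - p)))
        return grad, hess

    beta = 0.0
    hess = -1.0
    for _ in range(100):
        grad, hess = derivatives(beta)
        if hess >= 0:
            break
        step = -grad / hess
        beta += float(np.clip(step, -2.0, 2.0))
        if abs(step) < 1e-12:
            break
    se = math.sqrt(-1.0 / hess) if hess < 0 else float("nan")
    return beta, se


def cox_hr(times, events, group, ties: str = "efron") -> SurvivalSummary:
    """Cox proportional-hazards HR for a binary group indicator.

    ``group`` is 1 for the high-count ("at risk") group.  Ties are handled by
    the Efron correction by default (``ties="breslow"`` switches convention).
    The 95% CI comes from the observed information (Wald).  Raises if either
    group is empty or there are no events; a monotone likelihood (all events
    in one group) is returned flagged ``converged=False`` rather than as a
    silent estimate.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    t, e = _as_arrays(times, events)
    g = np.asarray(group, dtype=int)
    if not np.isin(g, (0, 1)).all():
        raise ValueError("group must be binary")
    if g.all() or not g.any():
        raise ValueError("both groups must be non-empty")
    if e.sum() == 0:
        raise ValueError("no events observed")

    med_low = km_median(t[g == 0], e[g == 0])
    med_high = km_median(t[g == 1], e[g == 1])
    base = dict(
        median_os_low_group=med_low,
        median_os_high_group=med_high,
        n_high=int(g.sum()),
        n_low=int((1 - g).sum()),
        n_events=int(e.sum()),
    )

    # all events in one group: the partial likelihood is monotone in beta
    if e[g == 0].sum() == 0 or e[g == 1].sum() == 0:
        return SurvivalSummary(
            hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            converged=False, **base,
        )

    if ties == "breslow":
        beta, se = _breslow_fit(t, e, g)
    else:
        df = pd.DataFrame({"time": t, "event": e, "group": g})
        cph = CoxPHFitter()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cph.fit(
                    df, duration_col="time", event_col="event",
                    fit_options={"precision": 1e-11},
                )
            except Exception:
                return SurvivalSummary(
                    hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                    converged=False, **base,
                )
        beta = float(cph.params_["group"])
        se = float(cph.standard_errors_["group"])
    if not (np.isfinite(beta) and np.isfinite(se)):
        return SurvivalSummary(
            hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
            converged=False, **base,
        )
    z = stats.norm.ppf(0.975)
    with np.errstate(over="ignore"):
        return SurvivalSummary(
            hr=float(np.exp(beta)),
            ci_low=float(np.exp(beta - z * se)),
            ci_high=float(np.exp(beta + z * se)),
            **base,
        )


def dichotomize(counts, cutoff: float | None = None) -> tuple[np.ndarray, float]:
    """Split counts into two groups: 1 iff ``count >= cutoff``.

    With ``cutoff=None`` the sample median is used (the training-time
    convention, which balances the at-risk and not-at-risk groups).  Returns
    ``(group, cutoff_used)``; a degenerate split (one empty group) is allowed
    and left to the caller to flag.
    """
    c = np.asarray(counts, dtype=float)
    if cutoff is None:
        cutoff = float(np.median(c))
    if cutoff < 0:
        raise ValueError("cutoff must be nonnegative")
    return (c >= cutoff).astype(int), float(cutoff)


def linear_regression(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x; returns (slope, intercept, R²).

    R² is the squared Pearson correlation.  ``x`` is the manual count and
    ``y`` the automated count in the intended use.  A constant ``y`` gives
    slope 0 and R² 0; a constant ``x`` is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x must not be constant")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def derive_cutoff(
    slope: float, intercept: float, reference_cutoff: float = 5
) -> int:
    """Translate the routine manual-count cut-off into an automated-count
    cut-off via the fitted regression line, rounded to the nearest positive
    integer (results below 1 clamp to 1)."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    value = slope * reference_cutoff + intercept
    cut = int(math.floor(value + 0.5))
    if cut < 1:
        warnings.warn("derived cut-off below 1; clamped to 1", stacklevel=2)
        return 1
    return cut


def cutoff_table(
    cohort: pd.DataFrame,
    cutoffs=range(1, 11),
    count_cols: tuple[str, ...] = ("count_auto", "count_manual"),
    time_col: str = "os_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """HR and median-OS table over fixed count cut-offs.

    One row per (cut-off, count column): n and % of patients at or above the
    cut-off, median OS below / at-or-above, HR with 95% CI.  Degenerate
    dichotomies (an empty group or a monotone likelihood) are flagged in the
    ``degenerate`` column, never dropped.
    """
    t = cohort[time_col].to_numpy(dtype=float)
    e = cohort[event_col].to_numpy(dtype=int)
    n = len(cohort)
    rows = []
    for cut in cutoffs:
        for col in count_cols:
            counts = cohort[col].to_numpy(dtype=float)
            group, _ = dichotomize(counts, cut)
            n_high = int(group.sum())
            row = {
                "cutoff": cut, "count_type": col,
                "n_at_or_above": n_high,
                "pct_at_or_above": 100.0 * n_high / n,
                "median_os_below": float("nan"),
                "median_os_at_or_above": float("nan"),
                "hr": float("nan"), "ci_low": float("nan"),
                "ci_high": float("nan"), "degenerate": False,
            }
            if n_high in (0, n):
                row["degenerate"] = True
            else:
                summ = cox_hr(t, e, group)
                row.update(
                    median_os_below=summ.median_os_low_group,
                    median_os_at_or_above=summ.median_os_high_group,
                    hr=summ.hr, ci_low=summ.ci_low, ci_high=summ.ci_high,
                    degenerate=not summ.converged,
                )
            rows.append(row)
    return pd.DataFrame(rows)
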