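"""Nonparametric and (semi)parametric survival summaries for lifespan cohorts.

Kaplan–Meier curves and Cox proportional hazards are delegated to lifelines;
the Weibull accelerated-failure-time (AFT) model is fitted in-package by
profile likelihood — given the shape, the per-group scale MLE is closed form —
which makes the estimated time ratio exactly equivariant under a proportional
rescaling of one group's times.

The "maximum survival" of a cohort is reported under both circulating
conventions: the single longest-lived animal and the mean of the top decile.
Quantile (e.g. 10% survival) differences between groups are tested with the
Wang–Allison construction: a 2×2 Fisher exact test of counts above/below the
pooled quantile threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from scipy import optimize, stats

from rapalife.mortality import CohortSurvival


class MonotoneLikelihoodError(RuntimeError):
    """Cox partial likelihood is monotone (complete separation of death order)."""


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray


@dataclass
class SurvivalSummary:
    mean: float
    q80: float
    q50: float
    q10: float
    max_longest: float
    max_top_decile_mean: float
    undefined_quantiles: tuple = ()


@dataclass
class CoxResult:
    coefficient: float
    hazard_ratio: float
    percent_risk_reduction: float
    se: float
    p: float
    converged: bool


@dataclass
class WeibullAFTResult:
    shape: float
    scale: float
    coefficient: float
    time_ratio: float
    percent_extension: float
    p: float
    converged: bool
    se_log_tr: float = float("nan")

    @property
    def ci_time_ratio(self) -> tuple[float, float]:
        """95% Wald interval for the time ratio (log scale)."""
        lo = self.coefficient - 1.959963984540054 * self.se_log_tr
        hi = self.coefficient + 1.959963984540054 * self.se_log_tr
        return float(np.exp(lo)), float(np.exp(hi))


def km_estimate(cohort: CohortSurvival) -> KMCurve:
    """Product-limit (Kaplan–Meier) survival estimate.

    Censored animals leave the risk set without a drop in the curve.
    """
    if len(cohort) == 0:
        raise ValueError("cannot estimate a survival curve from an empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(cohort.ages, event_observed=cohort.events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(float)
    surv = sf.iloc[:, 0].to_numpy(float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
    return KMCurve(times=times, survival=surv, at_risk=at_risk)


def _km_quantile(curve: KMCurve, events: np.ndarray, ages: np.ndarray, level: float) -> float:
    """Smallest observed event time t with S_KM(t) <= level; NaN if unreached."""
    event_times = np.unique(ages[events])
    for t in event_times:
        s = curve.survival[np.searchsorted(curve.times, t, side="right") - 1]
        if s <= level + 1e-12:
            return float(t)
    return float("nan")


def survival_summary(cohort: CohortSurvival) -> SurvivalSummary:
    """Mean, 80%/50%/10% survival ages and both maximum-survival conventions.

    The mean is the area under the KM curve up to the largest event time; the
    level-q age is the smallest event time where the KM curve has fallen to q
    or below.  Quantiles the curve never reaches (heavy censoring) are
    returned as NaN and listed in ``undefined_quantiles``.
    """
    if len(cohort) < 10:
        warnings.warn("fewer than 10 animals: the 10% survival age is unreliable")
    curve = km_estimate(cohort)
    qs = {}
    undefined = []
    for name, level in (("q80", 0.8), ("q50", 0.5), ("q10", 0.1)):
        q = _km_quantile(curve, cohort.events, cohort.ages, level)
        qs[name] = q
        if np.isnan(q):
            undefined.append(name)
    if undefined:
        warnings.warn(f"KM curve never reaches level(s) {undefined}; quantile undefined")

    # restricted mean: integrate the step function to the largest event time
    t_max = cohort.ages[cohort.events].max()
    ts = np.concatenate([curve.times[curve.times <= t_max], [t_max]])
    ss = np.concatenate([curve.survival[curve.times <= t_max], [0.0]])[:-1]
    mean = float(np.sum(np.diff(ts) * ss[: len(ts) - 1]))

    event_ages = np.sort(cohort.ages[cohort.events])
    k = max(1, len(cohort) // 10)
    return SurvivalSummary(
        mean=mean, **qs,
        max_longest=float(event_ages[-1]),
        max_top_decile_mean=float(event_ages[-k:].mean()),
        undefined_quantiles=tuple(undefined),
    )


def quantile_survival_test(cohort_1: CohortSurvival, cohort_2: CohortSurvival,
                           level: float = 0.1) -> float:
    """Wang–Allison-style test for a difference in the level-q survival age.

    Pools both cohorts, finds the smallest pooled event time where the pooled
    KM curve is <= level, cross-tabulates animals strictly above vs at/below
    that threshold by group, and returns the two-sided Fisher exact p.
    Censored animals below the threshold are excluded with a warning.
    """
    pooled = cohort_1.concat(cohort_2)
    curve = km_estimate(pooled)
    thr = _km_quantile(curve, pooled.events, pooled.ages, level)
    if np.isnan(thr):
        warnings.warn("pooled KM never reaches the requested level; returning p=1")
        return 1.0

    def counts(c: CohortSurvival):
        drop = (~c.events) & (c.ages <= thr)
        if drop.any():
            warnings.warn(f"excluding {int(drop.sum())} animal(s) censored below the threshold")
        keep = ~drop
        above = int(np.sum(c.ages[keep] > thr))
        below = int(np.sum(c.ages[keep] <= thr))
        return above, below

    a1, b1 = counts(cohort_1)
    a2, b2 = counts(cohort_2)
    table = np.array([[a1, b1], [a2, b2]])
    if table.sum(axis=0).min() == 0:
        warnings.warn("degenerate quantile table (all animals on one side); p=1")
        return 1.0
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def cox_ph(cohort_1: CohortSurvival, cohort_2: CohortSurvival) -> CoxResult:
    """Cox proportional hazards with a binary group covariate (Breslow ties).

    The covariate is 1 for ``cohort_2`` (treated) and 0 for ``cohort_1``
    (reference); percent risk reduction is (1 − HR)·100.  A monotone partial
    likelihood (complete separation of the death order) raises
    MonotoneLikelihoodError rather than returning a silently huge coefficient.
    """
    if cohort_1.n_events < 1 or cohort_2.n_events < 1:
        raise ValueError("need at least one event per group")
    df = pd.DataFrame({
        "duration": np.concatenate([cohort_1.ages, cohort_2.ages]),
        "event": np.concatenate([cohort_1.events, cohort_2.events]),
        "z": np.concatenate([np.zeros(len(cohort_1)), np.ones(len(cohort_2))]),
    })
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("ignore", category=DeprecationWarning)
            cph.fit(df, duration_col="duration", event_col="event")
    except (ConvergenceError, RuntimeWarning, Warning) as exc:
        raise MonotoneLikelihoodError(
            f"Cox partial likelihood did not converge (possible complete separation): {exc}"
        ) from exc
    beta = float(cph.params_["z"])
    se = float(cph.standard_errors_["z"])
    if abs(beta) > 15 or not np.isfinite(se) or se > 100:
        raise MonotoneLikelihoodError(
            f"Cox coefficient diverged (beta={beta:.3g}, se={se:.3g}); "
            "the partial likelihood is monotone")
    hr = float(np.exp(beta))
    return CoxResult(
        coefficient=beta, hazard_ratio=hr,
        percent_risk_reduction=(1.0 - hr) * 100.0,
        se=se, p=float(cph.summary.loc["z", "p"]), converged=True,
    )


def _weibull_profile_logl(log_k: float, groups) -> float:
    """Profile log-likelihood of a shared-shape Weibull over groups.

    Given shape k, the scale MLE per group is (Σ t_i^k / d_g)^{1/k} (the sum
    runs over all animals, d_g counts events); substituting it collapses the
    likelihood to a 1-D function of k.
    """
    k = np.exp(log_k)
    ll = 0.0
    for t, d in groups:
        d_g = d.sum()
        S = np.power(t, k).sum()
        ll += d_g * np.log(k) - d_g * np.log(S / d_g) + (k - 1.0) * np.log(t[d]).sum() - d_g
    return ll


def _weibull_full_logl(theta: np.ndarray, groups) -> float:
    """Log-likelihood in (log shape, log scale per group)."""
    k = np.exp(theta[0])
    ll = 0.0
    for (t, d), log_lam in zip(groups, theta[1:]):
        lam = np.exp(log_lam)
        d_g = d.sum()
        z = (t / lam) ** k
        ll += d_g * np.log(k) - d_g * k * log_lam + (k - 1.0) * np.log(t[d]).sum() - z.sum()
    return ll


def _fit_weibull_groups(groups) -> tuple[float, list[float], float]:
    """Shared-shape Weibull MLE; returns (shape, per-group scales, logL)."""
    res = optimize.minimize_scalar(
        lambda lk: -_weibull_profile_logl(lk, groups),
        bounds=(np.log(1e-2), np.log(1e3)), method="bounded",
        options={"xatol": 1e-13},
    )
    k = float(np.exp(res.x))
    scales = [float((np.power(t, k).sum() / d.sum()) ** (1.0 / k)) for t, d in groups]
    return k, scales, -float(res.fun)


def weibull_aft(cohort_1: CohortSurvival, cohort_2: CohortSurvival) -> WeibullAFTResult:
    """Weibull accelerated-failure-time fit with a binary group covariate.

    Both groups share the Weibull shape; the covariate multiplies event times
    by the time ratio TR = scale₂/scale₁, so percent lifespan extension is
    (TR − 1)·100.  Because the per-group scale MLE is closed form given the
    shape, TR is exact under a proportional time rescaling of one group.
    The p-value is a likelihood-ratio test of TR = 1 (shared scale, 1 df).
    """
    for c in (cohort_1, cohort_2):
        if c.n_events < 5:
            raise ValueError("need at least 5 events per group for a Weibull AFT fit")
    groups = [(cohort_1.ages, cohort_1.events), (cohort_2.ages, cohort_2.events)]
    k, (s1, s2), ll_free = _fit_weibull_groups(groups)
    pooled = (np.concatenate([cohort_1.ages, cohort_2.ages]),
              np.concatenate([cohort_1.events, cohort_2.events]))
    _, _, ll_null = _fit_weibull_groups([pooled])
    stat = max(0.0, 2.0 * (ll_free - ll_null))
    p = float(stats.chi2.sf(stat, 1))
    tr = s2 / s1

    # Wald SE of log TR from the observed information at the MLE
    theta = np.array([np.log(k), np.log(s1), np.log(s2)])
    h = 1e-5
    H = np.zeros((3, 3))
    for i in range(3):
        for j in range(i, 3):
            ei, ej = np.zeros(3), np.zeros(3)
            ei[i], ej[j] = h, h
            H[i, j] = H[j, i] = (
                _weibull_full_logl(theta + ei + ej, groups)
                - _weibull_full_logl(theta + ei - ej, groups)
                - _weibull_full_logl(theta - ei + ej, groups)
                + _weibull_full_logl(theta - ei - ej, groups)
            ) / (4.0 * h * h)
    try:
        cov = np.linalg.inv(-H)
        se = float(np.sqrt(cov[1, 1] + cov[2, 2] - 2.0 * cov[1, 2]))
    except np.linalg.LinAlgError:
        se = float("nan")
    return WeibullAFTResult(
        shape=k, scale=s1, coefficient=float(np.log(tr)), time_ratio=tr,
        percent_extension=(tr - 1.0) * 100.0, p=p,
        converged=bool(np.isfinite(ll_free)), se_log_tr=se,
    )
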