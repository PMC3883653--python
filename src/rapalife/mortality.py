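"""Maximum-likelihood fitting of the Gompertz family of mortality models.

The family comprises four nested hazard models for ages-at-death ``x`` (time
origin at treatment start):

* ``gompertz``             u(x) = a·e^{bx}
* ``gompertz_makeham``     u(x) = c + a·e^{bx}
* ``logistic``             u(x) = a·e^{bx} / (1 + (a·s/b)(e^{bx} − 1))
* ``logistic_makeham``     u(x) = c + a·e^{bx} / (1 + (a·s/b)(e^{bx} − 1))

``a`` is the initial mortality rate (1/month) at the time origin, ``b`` the
exponential rate of increase of the hazard — the demographic "rate of aging" —
``c`` an additive age-independent (Makeham) hazard and ``s`` a dimensionless
late-life deceleration parameter (the logistic hazard plateaus at b/s).

Model selection walks the nesting lattice with likelihood-ratio tests and
retains the least-parameterized model not significantly improved upon by any
of its extensions.  Group comparisons constrain ``a``, ``b`` or both to be
shared between two cohorts and refer 2·ΔlogL to a chi-square distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

FAMILIES = ("gompertz", "gompertz_makeham", "logistic", "logistic_makeham")

# number of free parameters per family
N_PARAMS = {
    "gompertz": 2,
    "gompertz_makeham": 3,
    "logistic": 3,
    "logistic_makeham": 4,
}

# direct-extension edges of the nesting lattice (base, extension)
NESTING = (
    ("gompertz", "gompertz_makeham"),
    ("gompertz", "logistic"),
    ("gompertz_makeham", "logistic_makeham"),
    ("logistic", "logistic_makeham"),
)


@dataclass(frozen=True)
class GompertzFamilyModel:
    """A parameterized member of the Gompertz mortality family."""

    family: str
    a: float
    b: float
    c: float | None = None
    s: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if not (np.isfinite(self.a) and self.a > 0):
            raise ValueError(f"parameter a must be positive and finite, got {self.a}")
        if not (np.isfinite(self.b) and self.b > 0):
            raise ValueError(f"parameter b must be positive and finite, got {self.b}")
        if self.family.endswith("makeham"):
            if self.c is None or not (np.isfinite(self.c) and self.c >= 0):
                raise ValueError(f"parameter c must be non-negative for {self.family}, got {self.c}")
        elif self.c is not None:
            raise ValueError(f"parameter c is not part of the {self.family} model")
        if self.family.startswith("logistic"):
            if self.s is None or not (np.isfinite(self.s) and self.s > 0):
                raise ValueError(f"parameter s must be positive for {self.family}, got {self.s}")
        elif self.s is not None:
            raise ValueError(f"parameter s is not part of the {self.family} model")

    @property
    def n_params(self) -> int:
        return N_PARAMS[self.family]


@dataclass(frozen=True)
class CohortSurvival:
    """Per-animal ages at death (months since treatment start) with event flags."""

    ages: np.ndarray
    events: np.ndarray
    sex: np.ndarray | None = None
    diet: np.ndarray | None = None

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=float)
        events = np.asarray(self.events, dtype=bool)
        if ages.ndim != 1 or ages.shape != events.shape:
            raise ValueError("ages and events must be 1-D arrays of equal length")
        if np.any(ages <= 0) or not np.all(np.isfinite(ages)):
            raise ValueError("all ages must be strictly positive and finite")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "events", events)

    def __len__(self) -> int:
        return self.ages.size

    @property
    def n_events(self) -> int:
        return int(self.events.sum())

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, age_col: str = "age_at_death_months",
                       event_col: str = "event") -> "CohortSurvival":
        sex = df["sex"].to_numpy() if "sex" in df else None
        diet = df["diet"].to_numpy() if "diet" in df else None
        return cls(df[age_col].to_numpy(float), df[event_col].to_numpy(bool), sex, diet)

    def subset(self, mask: np.ndarray) -> "CohortSurvival":
        return CohortSurvival(
            self.ages[mask], self.events[mask],
            None if self.sex is None else self.sex[mask],
            None if self.diet is None else self.diet[mask],
        )

    def concat(self, other: "CohortSurvival") -> "CohortSurvival":
        def cat(u, v):
            if u is None or v is None:
                return None
            return np.concatenate([u, v])
        return CohortSurvival(
            np.concatenate([self.ages, other.ages]),
            np.concatenate([self.events, other.events]),
            cat(self.sex, other.sex), cat(self.diet, other.diet),
        )


@dataclass
class FitResult:
    model: GompertzFamilyModel
    log_likelihood: float
    n: int
    converged: bool
    n_starts_used: int = 1


@dataclass
class ModelSelection:
    fits: dict
    chosen: str
    lrt_table: pd.DataFrame


@dataclass
class GroupComparison:
    tested_parameter: str
    logL_free: float
    logL_constrained: float
    statistic: float
    df: int
    p: float
    free_models: tuple
    constrained_models: tuple


# ---------------------------------------------------------------------------
# hazard / survival / likelihood
# ---------------------------------------------------------------------------

def hazard(model: GompertzFamilyModel, x) -> np.ndarray:
    """Instantaneous mortality rate u(x) at age x months past the time origin."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age x must be non-negative")
    a, b = model.a, model.b
    ebx = np.exp(b * x)
    if model.family == "gompertz":
        h = a * ebx
    elif model.family == "gompertz_makeham":
        h = model.c + a * ebx
    elif model.family == "logistic":
        h = a * ebx / (1.0 + (a * model.s / b) * (ebx - 1.0))
    else:  # logistic_makeham
        h = model.c + a * ebx / (1.0 + (a * model.s / b) * (ebx - 1.0))
    return h if h.shape else float(h)


def cumulative_hazard(model: GompertzFamilyModel, x) -> np.ndarray:
    """Integrated hazard H(x) = ∫₀ˣ u(t) dt, in closed form for every family."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("age x must be non-negative")
    a, b = model.a, model.b
    ebx = np.exp(b * x)
    if model.family == "gompertz":
        H = (a / b) * (ebx - 1.0)
    elif model.family == "gompertz_makeham":
        H = model.c * x + (a / b) * (ebx - 1.0)
    elif model.family == "logistic":
        H = np.log1p((a * model.s / b) * (ebx - 1.0)) / model.s
    else:
        H = model.c * x + np.log1p((a * model.s / b) * (ebx - 1.0)) / model.s
    return H if H.shape else float(H)


def survival(model: GompertzFamilyModel, x) -> np.ndarray:
    """Survivorship S(x) = exp(−H(x)); S(0) = 1 and monotone non-increasing."""
    S = np.exp(-np.asarray(cumulative_hazard(model, x)))
    return S if S.shape else float(S)


def log_likelihood(model: GompertzFamilyModel, cohort: CohortSurvival) -> float:
    """Censored log-likelihood: Σ_deaths [ln u(x) − H(x)] + Σ_censored −H(x)."""
    x, d = cohort.ages, cohort.events
    H = np.asarray(cumulative_hazard(model, x))
    with np.errstate(divide="ignore"):
        lnh = np.log(np.asarray(hazard(model, x[d])))
    return float(lnh.sum() - H.sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_LOG_B_BOUNDS = (np.log(1e-6), np.log(10.0))


def _gompertz_profile_negll(log_b: float, x: np.ndarray, d: np.ndarray):
    """Negative profile log-likelihood in b; a is profiled out in closed form.

    With H(x) = (a/b)(e^{bx}−1), ∂logL/∂a = n_d/a − (1/b)Σ(e^{bx}−1) gives
    â(b) = n_d·b / Σ(e^{bx}−1).
    """
    b = np.exp(log_b)
    n_d = d.sum()
    expm = np.expm1(b * x)
    denom = expm.sum()
    a = n_d * b / denom
    ll = n_d * np.log(a) + b * x[d].sum() - (a / b) * denom
    return -ll, a


def _fit_gompertz(cohort: CohortSurvival) -> FitResult:
    x, d = cohort.ages, cohort.events
    res = optimize.minimize_scalar(
        lambda lb: _gompertz_profile_negll(lb, x, d)[0],
        bounds=_LOG_B_BOUNDS, method="bounded",
        options={"xatol": 1e-12},
    )
    b = float(np.exp(res.x))
    a = float(_gompertz_profile_negll(res.x, x, d)[1])
    model = GompertzFamilyModel("gompertz", a=a, b=b)
    return FitResult(model, -float(res.fun), len(cohort), bool(res.success), 1)


def _pack(family: str, model: GompertzFamilyModel) -> np.ndarray:
    v = [np.log(model.a), np.log(model.b)]
    if family.endswith("makeham"):
        v.append(np.log(max(model.c, 1e-12)))
    if family.startswith("logistic"):
        v.append(np.log(model.s))
    return np.array(v)


def _unpack(family: str, theta: np.ndarray) -> GompertzFamilyModel:
    a, b = np.exp(theta[0]), np.exp(theta[1])
    c = s = None
    i = 2
    if family.endswith("makeham"):
        c = float(np.exp(theta[i])); i += 1
    if family.startswith("logistic"):
        s = float(np.exp(theta[i]))
    return GompertzFamilyModel(family, a=float(a), b=float(b), c=c, s=s)


def fit_model(cohort: CohortSurvival, family: str = "gompertz", *,
              n_starts: int = 8, tolerance: float = 1e-10, seed: int = 0,
              min_events: int = 5) -> FitResult:
    """Fit one family to a cohort by maximum likelihood.

    The two-parameter Gompertz model is fitted by exact 1-D profile likelihood.
    The extended families are fitted by Nelder–Mead in log-parameter space with
    multiple deterministic starts; the first start places the extra parameters
    at 1e-8 on top of the Gompertz MLE, so the extension's likelihood can never
    fall below the base model's (the LRT statistic stays non-negative).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if cohort.n_events < min_events:
        raise ValueError(f"need at least {min_events} events to fit, got {cohort.n_events}")

    base = _fit_gompertz(cohort)
    if family == "gompertz":
        return base

    x, d = cohort.ages, cohort.events

    def negll(theta):
        try:
            m = _unpack(family, theta)
        except (ValueError, OverflowError):
            return np.inf
        with np.errstate(over="ignore", invalid="ignore"):
            ll = log_likelihood(m, cohort)
        return -ll if np.isfinite(ll) else np.inf

    tiny = np.log(1e-8)
    starts = []
    m0 = base.model
    if family == "gompertz_makeham":
        starts.append(np.array([np.log(m0.a), np.log(m0.b), tiny]))
    elif family == "logistic":
        starts.append(np.array([np.log(m0.a), np.log(m0.b), tiny]))
    else:
        starts.append(np.array([np.log(m0.a), np.log(m0.b), tiny, tiny]))
    rng = np.random.default_rng(seed)
    while len(starts) < n_starts:
        starts.append(starts[0] + rng.normal(0.0, 0.7, size=starts[0].size))

    best = None
    n_used = 0
    for theta0 in starts:
        n_used += 1
        res = optimize.minimize(
            negll, theta0, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": tolerance, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res

    ll = -float(best.fun)
    converged = bool(best.success) and np.isfinite(ll)
    # the multi-start search must never end below its own starting point
    if ll < base.log_likelihood - 1e-6:
        converged = False
    model = _unpack(family, best.x)
    return FitResult(model, ll, len(cohort), converged, n_used)


def select_model(cohort: CohortSurvival, alpha: float = 0.05, *,
                 n_starts: int = 8, seed: int = 0) -> ModelSelection:
    """Fit all four families and choose by likelihood-ratio tests.

    Walks up the nesting lattice from the two-parameter Gompertz model,
    moving to an extension only when the LRT rejects the simpler model at
    ``alpha``; the least-parameterized unrejected model is retained.
    """
    fits = {fam: fit_model(cohort, fam, n_starts=n_starts, seed=seed) for fam in FAMILIES}
    rows = []
    pairs = list(NESTING) + [("gompertz", "logistic_makeham")]
    for base, ext in pairs:
        fb, fe = fits[base], fits[ext]
        df = N_PARAMS[ext] - N_PARAMS[base]
        if not (fb.converged and fe.converged):
            rows.append((base, ext, np.nan, df, np.nan, False))
            continue
        stat = max(0.0, 2.0 * (fe.log_likelihood - fb.log_likelihood))
        p = float(stats.chi2.sf(stat, df))
        rows.append((base, ext, stat, df, p, True))
    lrt = pd.DataFrame(rows, columns=["base", "extension", "statistic", "df", "p", "available"])

    chosen = "gompertz"
    while True:
        cand = lrt[(lrt["base"] == chosen) & lrt["available"] & (lrt["p"] < alpha)
                   & (lrt["df"] == 1)]
        if cand.empty:
            break
        ext = cand.loc[cand["p"].idxmin(), "extension"]
        if not fits[ext].converged:
            break
        chosen = ext
    return ModelSelection(fits=fits, chosen=chosen, lrt_table=lrt)


# ---------------------------------------------------------------------------
# group comparisons (two-parameter Gompertz)
# ---------------------------------------------------------------------------

def _two_group_profile_negll_shared_b(log_b, groups):
    """Shared b, free a per group; each a profiled in closed form."""
    b = np.exp(log_b)
    ll = 0.0
    for x, d in groups:
        n_d = d.sum()
        denom = np.expm1(b * x).sum()
        a = n_d * b / denom
        ll += n_d * np.log(a) + b * x[d].sum() - (a / b) * denom
    return -ll


def _two_group_negll_shared_a(log_bs, groups):
    """Shared a, free b per group; the common a profiled in closed form."""
    bs = np.exp(log_bs)
    n_d = sum(d.sum() for _, d in groups)
    Q = sum(np.expm1(b * x).sum() / b for b, (x, d) in zip(bs, groups))
    a = n_d / Q
    ll = n_d * np.log(a) - a * Q
    ll += sum(b * x[d].sum() for b, (x, d) in zip(bs, groups))
    return -ll


def compare_groups(cohort_1: CohortSurvival, cohort_2: CohortSurvival,
                   tested_parameter: str = "both", *, family: str = "gompertz",
                   alpha_refit_starts: int = 32) -> GroupComparison:
    """Likelihood-ratio test for a difference in Gompertz parameters.

    The free model fits separate (a, b) to each cohort; the constrained model
    shares the tested parameter(s).  2·(logL_free − logL_constrained) is
    referred to chi-square with 1 df (a or b) or 2 df (both).  Pool labels
    (e.g. sexes) before calling to reproduce a combined-sex comparison.
    """
    if family != "gompertz":
        raise NotImplementedError("group comparisons are defined for the two-parameter Gompertz model")
    if tested_parameter not in ("a", "b", "both"):
        raise ValueError("tested_parameter must be 'a', 'b' or 'both'")

    f1 = _fit_gompertz(cohort_1)
    f2 = _fit_gompertz(cohort_2)
    logL_free = f1.log_likelihood + f2.log_likelihood
    groups = [(cohort_1.ages, cohort_1.events), (cohort_2.ages, cohort_2.events)]

    if tested_parameter == "both":
        pooled = cohort_1.concat(cohort_2)
        fc = _fit_gompertz(pooled)
        logL_con = fc.log_likelihood
        con_models = (fc.model, fc.model)
        df = 2
    elif tested_parameter == "b":
        res = optimize.minimize_scalar(
            _two_group_profile_negll_shared_b, args=(groups,),
            bounds=_LOG_B_BOUNDS, method="bounded", options={"xatol": 1e-12},
        )
        logL_con = -float(res.fun)
        b = float(np.exp(res.x))
        models = []
        for x, d in groups:
            a = float(d.sum() * b / np.expm1(b * x).sum())
            models.append(GompertzFamilyModel("gompertz", a=a, b=b))
        con_models = tuple(models)
        df = 1
    else:  # shared a
        x0 = np.log([f1.model.b, f2.model.b])
        res = optimize.minimize(
            _two_group_negll_shared_a, x0, args=(groups,), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        logL_con = -float(res.fun)
        bs = np.exp(res.x)
        n_d = cohort_1.n_events + cohort_2.n_events
        Q = sum(np.expm1(b * x).sum() / b for b, (x, d) in zip(bs, groups))
        a = float(n_d / Q)
        con_models = tuple(GompertzFamilyModel("gompertz", a=a, b=float(b)) for b in bs)
        df = 1

    stat = 2.0 * (logL_free - logL_con)
    if stat < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic ({stat:.3g}); constrained optimum exceeds the free fit")
    stat = max(0.0, stat)
    p = float(stats.chi2.sf(stat, df))
    return GroupComparison(tested_parameter, logL_free, logL_con, stat, df, p,
                           (f1.model, f2.model), con_models)
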