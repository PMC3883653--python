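import numpy as np
import pandas as pd
import pytest

from rapalife.mortality import CohortSurvival, GompertzFamilyModel
from rapalife.synthetic_data import ExpressionDesign, sample_death_times, simulate_expression


@pytest.fixture(scope="session")
def gompertz_model():
    return GompertzFamilyModel("gompertz", a=0.001, b=0.2)


@pytest.fixture(scope="session")
def large_gompertz_cohort(gompertz_model):
    """n=5,000 uncensored deaths from (a=0.001, b=0.2), fixed seed."""
    rng = np.random.default_rng(42)
    t = sample_death_times(gompertz_model, 5000, rng)
    return CohortSurvival(t, np.ones(5000, dtype=bool))


@pytest.fixture(scope="session")
def small_expression():
    """A compact simulated study: 4 groups, responder split, planted effects."""
    design = ExpressionDesign(n_probes=1200, seed=11)
    intensities, meta, truth = simulate_expression(design)
    return design, intensities, meta, truth


def orthogonal_procrustes_residual(X, Y):
    """RMS residual after the best rigid alignment (rotation/reflection +
    translation) of Y onto X; the scale is untouched."""
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    U, _, Vt = np.linalg.svd(Yc.T @ Xc)
    R = U @ Vt
    return float(np.sqrt(np.mean((Yc @ R - Xc) ** 2)))


def bh_oracle(p):
    """Exhaustive Benjamini–Hochberg step-up: adj_(i) = min_{j>=i} p_(j)·m/j, capped at 1."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
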