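"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from longmed import MediationDataset, SimulationConfig, simulate_dataset
from longmed.estimation import MediationFit, PathFit


def make_path_fit(coefs, intercept=(0.0, 0.1), tau_sq=0.1, sigma_sq=0.9,
                  n_subjects=50, n_obs=100):
    """Hand-constructed PathFit for interval tests that need exact inputs."""
    return PathFit(
        coefficients=dict(coefs),
        intercept=intercept,
        tau_sq_hat=tau_sq,
        sigma_sq_hat=sigma_sq,
        loglik=-100.0,
        converged=True,
        n_subjects=n_subjects,
        n_obs=n_obs,
    )


def make_mediation_fit(a, se_a, b, se_b):
    """MediationFit with prescribed path estimates and standard errors."""
    a_path = make_path_fit({"x": (a, se_a)})
    b_path = make_path_fit({"x": (0.0, 0.1), "m": (b, se_b)})
    return MediationFit(a_path=a_path, b_path=b_path)


def dense_profile_loglik(data: MediationDataset, outcome, predictors, tau2, sig2):
    """Marginal Gaussian log-likelihood with GLS coefficients profiled out.

    Independent oracle route: builds each subject's covariance matrix
    V = sig2*I + tau2*J explicitly, inverts it, and accumulates the GLS
    normal equations -- no eigen-decomposition, no profiling over the
    variance ratio.  tau2/sig2 may be arrays (a grid), vectorized over the
    leading axis.
    """
    cols = {"x": data.x, "m": data.m, "y": data.y}
    yv = cols[outcome]
    J, mm = yv.shape
    tau2 = np.atleast_1d(np.asarray(tau2, float))
    sig2 = np.atleast_1d(np.asarray(sig2, float))
    G = tau2.size
    V = sig2[:, None, None] * np.eye(mm) + tau2[:, None, None] * np.ones((mm, mm))
    Vi = np.linalg.inv(V)
    sign, logdet = np.linalg.slogdet(V)
    p = 1 + len(predictors)
    X = np.stack(
        [np.ones((J, mm))] + [cols[name] for name in predictors], axis=-1
    )  # (J, mm, p)
    XtVi = np.einsum("jma,gmn->gjna", X, Vi)  # (G, J, mm, p)
    info = np.einsum("gjma,jmb->gab", XtVi, X)
    rhs = np.einsum("gjma,jm->ga", XtVi, yv)
    beta = np.linalg.solve(info, rhs[..., None])[..., 0]
    resid = yv[None] - np.einsum("jmp,gp->gjm", X, beta)
    quad = np.einsum("gjm,gmn,gjn->g", resid, Vi, resid)
    ll = -0.5 * (J * mm * np.log(2 * np.pi) + J * logdet + quad)
    return ll, beta


def grid_ml_oracle(data, outcome, predictors, tau_max=2.0, sig_max=2.0):
    """Brute-force grid maximization of the profiled marginal likelihood.

    Coarse 0.02 grid over (tau2, sig2), refined to 1e-3 resolution around the
    coarse optimum.  Returns (loglik, beta, tau2, sig2) at the best grid
    point.
    """
    t = np.arange(0.0, tau_max, 0.02)
    s = np.arange(0.02, sig_max, 0.02)
    tt, ss = np.meshgrid(t, s, indexing="ij")
    ll, _ = dense_profile_loglik(data, outcome, predictors, tt.ravel(), ss.ravel())
    k = np.argmax(ll)
    t0, s0 = tt.ravel()[k], ss.ravel()[k]
    t = np.clip(np.arange(t0 - 0.021, t0 + 0.021, 0.001), 0.0, None)
    s = np.clip(np.arange(s0 - 0.021, s0 + 0.021, 0.001), 1e-4, None)
    tt, ss = np.meshgrid(np.unique(t), np.unique(s), indexing="ij")
    ll, beta = dense_profile_loglik(data, outcome, predictors, tt.ravel(), ss.ravel())
    k = np.argmax(ll)
    return ll[k], beta[k], tt.ravel()[k], ss.ravel()[k]


@pytest.fixture
def small_dataset():
    """A fixed 6-subject x 2-measure dataset with a recorded seed."""
    cfg = SimulationConfig(
        beta_a=0.39, beta_b=0.39, icc=0.3, n_subjects=6, n_measures=2, seed=314,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def medium_dataset():
    """120 subjects x 3 measures, moderate effects."""
    cfg = SimulationConfig(
        beta_a=0.39, beta_b=0.39, icc=0.3, n_subjects=120, n_measures=3, seed=7,
    )
    return simulate_dataset(cfg)
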