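"""Maximum-likelihood estimation of the random-intercept path regressions.

For a balanced design (J subjects, m occasions) the random-intercept model

    y_j = X_j beta + u_j 1_m + e_j,   u_j ~ N(0, tau^2),  e_j ~ N(0, sigma^2 I)

has per-subject covariance V = sigma^2 I + tau^2 J_m (compound symmetry),
whose eigenvalues are lambda_1 = sigma^2 + m tau^2 on the within-subject mean
direction and lambda_2 = sigma^2 on its (m-1)-dimensional complement.  The
marginal Gaussian log-likelihood therefore separates into a between-subject
and a within-subject least-squares problem coupled only through the shared
coefficient vector, and can be profiled down to a one-dimensional search over
the eigenvalue ratio gamma = lambda_2 / lambda_1 in (0, 1]:

    beta(gamma)  = (W + gamma B)^{-1} (w_xy + gamma b_xy)
    lambda_1     = (SSW/gamma + SSB) / (J m)
    -2 log L     = J m log lambda_1 + J (m-1) log gamma + const

where W, B are within/between cross-product matrices and SSW, SSB the
corresponding residual sums of squares.  gamma = 1 is the tau^2 = 0 boundary
(a legitimate MLE, reported as tau_sq_hat = 0 with converged=True).  The
search uses a coarse log-scale grid followed by golden-section refinement and
is vectorized across a batch of datasets, which is what makes bootstrap and
Monte-Carlo power computation affordable.

Coefficient standard errors come from the inverse Fisher information at the
optimum, cov(beta) = (W/lambda_2 + B/lambda_1)^{-1}; for Gaussian mixed models
the information is block-diagonal between the mean and variance parameters, so
this is the usual ML standard error.  Estimation is ML, not REML.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datagen import MediationDataset

# column order of the cross-product blocks: intercept, x, m, y
_COL_INDEX = {"const": 0, "x": 1, "m": 2, "y": 3}

_GAMMA_MIN = 1e-8  # lower bound of the eigenvalue ratio (ICC -> 1 limit)
_TAU_FLOOR = 1e-10  # tau^2 estimates below this are reported as exactly 0
_N_GRID = 25  # coarse log-gamma grid points
_N_GOLDEN = 48  # golden-section iterations (bracket shrinks to ~1e-9)
_PARAB_H = 1e-3  # stencil half-width (log gamma) of the final parabolic polish


@dataclass
class PathFit:
    """One fitted path regression (random-intercept ML or single-level OLS)."""

    coefficients: dict[str, tuple[float, float]]
    intercept: tuple[float, float]
    tau_sq_hat: float
    sigma_sq_hat: float
    loglik: float
    converged: bool
    n_subjects: int
    n_obs: int
    method: str = "ml_random_intercept"

    def coef(self, name: str) -> float:
        return self.coefficients[name][0]

    def se(self, name: str) -> float:
        return self.coefficients[name][1]


@dataclass
class MediationFit:
    """Paired a-path (M ~ X) and b-path (Y ~ X + M) fits.

    ``ab_hat`` is the ML estimate of the mediation (indirect) effect
    beta_a * beta_b and ``sobel_se`` its first-order delta-method standard
    error sqrt(se_a^2 b^2 + se_b^2 a^2).
    """

    a_path: PathFit
    b_path: PathFit
    ab_hat: float = field(init=False)
    sobel_se: float = field(init=False)

    def __post_init__(self):
        a, se_a = self.a_path.coefficients["x"]
        b, se_b = self.b_path.coefficients["m"]
        self.ab_hat = a * b
        self.sobel_se = math.sqrt(se_a**2 * b**2 + se_b**2 * a**2)

    @property
    def converged(self) -> bool:
        return self.a_path.converged and self.b_path.converged

    @property
    def z_a(self) -> float:
        a, se_a = self.a_path.coefficients["x"]
        return a / se_a if se_a > 0 else math.inf * np.sign(a)

    @property
    def z_b(self) -> float:
        b, se_b = self.b_path.coefficients["m"]
        return b / se_b if se_b > 0 else math.inf * np.sign(b)


# ---------------------------------------------------------------------------
# batched sufficient statistics and the profiled compound-symmetry ML core
# ---------------------------------------------------------------------------


def subject_crossprods(x, m, y):
    """Per-subject total and between cross-products of the columns [1, x, m, y].

    Parameters are arrays broadcastable to shape (..., J, mm).  Returns
    ``(T, B)`` of shape (..., J, 4, 4): T_j = sum_i z_ij z_ij' and
    B_j = mm * zbar_j zbar_j'.  Any regression among the four columns, for any
    subset of subjects (hence any cases-bootstrap resample), is a function of
    sums of these blocks: W = sum(T - B), B = sum(B).
    """
    x = np.asarray(x, dtype=float)
    Z = np.stack([np.ones_like(x), x, np.asarray(m, float), np.asarray(y, float)], axis=-1)
    T = np.einsum("...ia,...ib->...ab", Z, Z)
    zbar = Z.mean(axis=-2)
    B = x.shape[-1] * np.einsum("...a,...b->...ab", zbar, zbar)
    return T, B


def _submatrices(W4, B4, pred_idx, out_idx):
    """Slice aggregated 4x4 within/between blocks to one regression problem."""
    p = list(pred_idx)
    Wpp = W4[..., p, :][..., :, p]
    Bpp = B4[..., p, :][..., :, p]
    wpy = W4[..., p, out_idx]
    bpy = B4[..., p, out_idx]
    wyy = W4[..., out_idx, out_idx]
    byy = B4[..., out_idx, out_idx]
    return Wpp, Bpp, wpy, bpy, wyy, byy


def _profile_neg2ll(gamma, Wpp, Bpp, wpy, bpy, wyy, byy, J, mm, reml=False):
    """-2 profile (restricted) log-likelihood, up to constants, at ratio gamma.

    gamma has shape (batch,) (or scalar); returns (f, beta, SSW, SSB).
    For REML the criterion gains the log-determinant of the GLS information
    and the variance divisor drops by the number of fixed effects p:
    using X'V^{-1}X = (W/gamma + B)/lambda_1 = (W + gamma B)/(gamma lambda_1),
    log|X'V^{-1}X| = log|W + gamma B| - p log(gamma lambda_1).
    """
    g = np.asarray(gamma, dtype=float)
    gm = g[..., None, None]
    M = Wpp + gm * Bpp
    v = wpy + g[..., None] * bpy
    beta = np.linalg.solve(M, v[..., None])[..., 0]
    SSW = wyy - 2.0 * np.einsum("...p,...p->...", beta, wpy) + np.einsum(
        "...p,...pq,...q->...", beta, Wpp, beta
    )
    SSB = byy - 2.0 * np.einsum("...p,...p->...", beta, bpy) + np.einsum(
        "...p,...pq,...q->...", beta, Bpp, beta
    )
    SSW = np.maximum(SSW, 1e-300)
    SSB = np.maximum(SSB, 1e-300)
    p = Wpp.shape[-1] if reml else 0
    lam1 = (SSW / g + SSB) / (J * mm - p)
    f = (J * mm - p) * np.log(lam1) + J * (mm - 1) * np.log(g)
    if reml:
        _, logdetM = np.linalg.slogdet(M)
        f = f + logdetM - p * np.log(g)
    return f, beta, SSW, SSB


def _ml_fit_cs(W4, B4, pred_idx, out_idx, J, mm, reml=False):
    """Batched ML/REML fit of the compound-symmetry random-intercept model.

    W4, B4: aggregated within/between 4x4 blocks, shape (batch, 4, 4).
    Returns a dict of batched arrays: beta (batch, p), se (batch, p),
    tau_sq, sigma_sq, loglik, ok (finite-result mask).
    """
    stats = _submatrices(W4, B4, pred_idx, out_idx)
    Wpp, Bpp = stats[0], stats[1]
    batch = Wpp.shape[:-2]

    # coarse grid on log(gamma), then golden-section refinement per element
    tgrid = np.linspace(np.log(_GAMMA_MIN), 0.0, _N_GRID)
    fgrid = np.empty(tgrid.shape + batch)
    for i, t in enumerate(tgrid):
        g = np.full(batch, np.exp(t))
        fgrid[i], *_ = _profile_neg2ll(g, *stats, J, mm, reml=reml)
    imin = np.nanargmin(fgrid, axis=0)
    lo = tgrid[np.maximum(imin - 1, 0)]
    hi = tgrid[np.minimum(imin + 1, _N_GRID - 1)]

    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.copy(), hi.copy()
    for _ in range(_N_GOLDEN):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, *_ = _profile_neg2ll(np.exp(c), *stats, J, mm, reml=reml)
        fd, *_ = _profile_neg2ll(np.exp(d), *stats, J, mm, reml=reml)
        take_c = fc < fd
        b = np.where(take_c, d, b)
        a = np.where(take_c, a, c)
    t_opt = (a + b) / 2.0

    # parabolic polish on a wide stencil: the golden-section endpoint wanders
    # within the machine-flat region of the objective, so the vertex of a
    # parabola through three well-separated points pins gamma as a smooth
    # function of the data (exact location-shift invariance of the estimates)
    t0 = np.clip(t_opt, np.log(_GAMMA_MIN) + _PARAB_H, -_PARAB_H)
    f_m, *_ = _profile_neg2ll(np.exp(t0 - _PARAB_H), *stats, J, mm, reml=reml)
    f_0, *_ = _profile_neg2ll(np.exp(t0), *stats, J, mm, reml=reml)
    f_p, *_ = _profile_neg2ll(np.exp(t0 + _PARAB_H), *stats, J, mm, reml=reml)
    curv = f_m - 2.0 * f_0 + f_p
    with np.errstate(divide="ignore", invalid="ignore"):
        step = 0.5 * _PARAB_H * (f_m - f_p) / curv
    refined = np.where(
        (curv > 0) & np.isfinite(step) & (np.abs(step) < 2 * _PARAB_H),
        t0 + step,
        t_opt,
    )
    t_star = np.clip(refined, np.log(_GAMMA_MIN), 0.0)
    # keep the refinement only where it does not worsen the objective
    f_ref, *_ = _profile_neg2ll(np.exp(t_star), *stats, J, mm, reml=reml)
    f_gold, *_ = _profile_neg2ll(np.exp(t_opt), *stats, J, mm, reml=reml)
    t_star = np.where(f_ref <= f_gold + 1e-9 * np.abs(f_gold), t_star, t_opt)
    gamma = np.exp(t_star)

    p_dof = Wpp.shape[-1] if reml else 0
    f, beta, SSW, SSB = _profile_neg2ll(gamma, *stats, J, mm, reml=reml)
    lam1 = (SSW / gamma + SSB) / (J * mm - p_dof)
    sigma_sq = gamma * lam1
    tau_sq = (lam1 - sigma_sq) / mm
    at_boundary = tau_sq < _TAU_FLOOR
    if np.any(at_boundary):
        # tau^2 = 0 boundary: refit with gamma = 1 exactly (pooled regression)
        g1 = np.ones(batch)
        f1, beta1, SSW1, SSB1 = _profile_neg2ll(g1, *stats, J, mm, reml=reml)
        lam1_1 = (SSW1 + SSB1) / (J * mm - p_dof)
        beta = np.where(at_boundary[..., None], beta1, beta)
        sigma_sq = np.where(at_boundary, lam1_1, sigma_sq)
        lam1 = np.where(at_boundary, lam1_1, lam1)
        tau_sq = np.where(at_boundary, 0.0, tau_sq)
        SSW, SSB = (
            np.where(at_boundary, SSW1, SSW),
            np.where(at_boundary, SSB1, SSB),
        )

    loglik = -0.5 * (
        (J * mm - p_dof) * math.log(2.0 * math.pi)
        + J * (mm - 1) * np.log(sigma_sq)
        + J * np.log(lam1)
        + SSW / sigma_sq
        + SSB / lam1
    )
    if reml:
        gm = gamma[..., None, None]
        _, logdetM = np.linalg.slogdet(Wpp + gm * Bpp)
        loglik = loglik - 0.5 * (
            logdetM - p_dof * (np.log(gamma) + np.log(lam1))
        )
    info = Wpp / sigma_sq[..., None, None] + Bpp / lam1[..., None, None]
    cov = np.linalg.inv(info)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=-2, axis2=-1), 0.0))
    ok = (
        np.all(np.isfinite(beta), axis=-1)
        & np.all(np.isfinite(se) & (se > 0), axis=-1)
        & np.isfinite(loglik)
    )
    return {
        "beta": beta,
        "se": se,
        "cov": cov,
        "tau_sq": tau_sq,
        "sigma_sq": sigma_sq,
        "loglik": loglik,
        "ok": ok,
    }


def _ols_fit_core(T4, pred_idx, out_idx, n):
    """Batched OLS on aggregated total cross-products T4 (batch, 4, 4).

    Classical (unbiased-variance) standard errors; log-likelihood at the
    Gaussian ML variance RSS/n.
    """
    p = list(pred_idx)
    Tpp = T4[..., p, :][..., :, p]
    tpy = T4[..., p, out_idx]
    tyy = T4[..., out_idx, out_idx]
    beta = np.linalg.solve(Tpp, tpy[..., None])[..., 0]
    rss = tyy - 2.0 * np.einsum("...p,...p->...", beta, tpy) + np.einsum(
        "...p,...pq,...q->...", beta, Tpp, beta
    )
    rss = np.maximum(rss, 0.0)
    dof = n - len(p)
    sigma_sq_unbiased = rss / dof
    cov = sigma_sq_unbiased[..., None, None] * np.linalg.inv(Tpp)
    se = np.sqrt(np.maximum(np.diagonal(cov, axis1=-2, axis2=-1), 0.0))
    sigma_sq_ml = rss / n
    with np.errstate(divide="ignore"):
        loglik = -0.5 * n * (np.log(2.0 * math.pi * sigma_sq_ml) + 1.0)
    ok = np.all(np.isfinite(beta), axis=-1) & np.all(np.isfinite(se), axis=-1)
    return {
        "beta": beta,
        "se": se,
        "cov": cov,
        "sigma_sq": sigma_sq_unbiased,
        "loglik": loglik,
        "ok": ok,
    }


# ---------------------------------------------------------------------------
# public single-dataset API
# ---------------------------------------------------------------------------


def _resolve_names(outcome: str, predictors: list[str]):
    for name in [outcome, *predictors]:
        if name not in ("x", "m", "y"):
            raise ValueError(f"unknown variable name {name!r}; use 'x', 'm' or 'y'")
    if outcome in predictors:
        raise ValueError("outcome cannot also be a predictor")
    pred_idx = (0,) + tuple(_COL_INDEX[p] for p in predictors)
    return pred_idx, _COL_INDEX[outcome]


def _pathfit_from_core(
    core, predictors, n_subjects, n_obs, method, means, outcome, tau_sq=None
):
    """Assemble a PathFit; undo the grand-mean centering on the intercept.

    Fits run on grand-mean-centered columns for numerical stability (the
    model is invariant to location shifts, but raw cross-products suffer
    cancellation when means are large).  With a balanced design the centered
    intercept is orthogonal to the centered covariates, so the uncentered
    intercept b0 = b0_c + mean(outcome) - sum_k mean(pred_k) b_k has variance
    w' Cov w with w = (1, -mean(pred)).
    """
    beta = np.asarray(core["beta"], float).reshape(-1)
    se = np.asarray(core["se"], float).reshape(-1)
    cov = np.asarray(core["cov"], float).reshape(len(beta), len(beta))
    coefs = {
        name: (float(beta[i + 1]), float(se[i + 1])) for i, name in enumerate(predictors)
    }
    pbar = np.array([means[p] for p in predictors])
    b0 = beta[0] + means[outcome] - float(pbar @ beta[1:])
    w = np.concatenate(([1.0], -pbar))
    se0 = float(np.sqrt(max(w @ cov @ w, 0.0)))
    return PathFit(
        coefficients=coefs,
        intercept=(float(b0), se0),
        tau_sq_hat=float(tau_sq) if tau_sq is not None else float(np.ravel(core["tau_sq"])[0]),
        sigma_sq_hat=float(np.ravel(core["sigma_sq"])[0]),
        loglik=float(np.ravel(core["loglik"])[0]),
        converged=bool(np.all(core["ok"])),
        n_subjects=n_subjects,
        n_obs=n_obs,
        method=method,
    )


def _centered_columns(data: MediationDataset):
    means = {
        "x": float(data.x.mean()),
        "m": float(data.m.mean()),
        "y": float(data.y.mean()),
    }
    return data.x - means["x"], data.m - means["m"], data.y - means["y"], means


def fit_random_intercept(
    data: MediationDataset, outcome: str, predictors: list[str],
    reml: bool = False,
) -> PathFit:
    """ML (default) or REML fit of a random-intercept regression.

    Maximizes the marginal Gaussian likelihood (or the restricted likelihood
    with ``reml=True``) under a compound-symmetry per-subject covariance;
    standard errors from the inverse information.  Delegates to
    :func:`fit_ols` when there is a single measure per subject.
    """
    if data.n_measures == 1:
        return fit_ols(data, outcome, predictors)
    if data.n_subjects < 3:
        raise ValueError("random-intercept estimation needs at least 3 subjects")
    pred_idx, out_idx = _resolve_names(outcome, predictors)
    xc, mc, yc, means = _centered_columns(data)
    T, B = subject_crossprods(xc, mc, yc)
    W4 = (T - B).sum(axis=0)[None]
    B4 = B.sum(axis=0)[None]
    core = _ml_fit_cs(
        W4, B4, pred_idx, out_idx, data.n_subjects, data.n_measures, reml=reml
    )
    return _pathfit_from_core(
        core, predictors, data.n_subjects, data.n_obs,
        "reml_random_intercept" if reml else "ml_random_intercept",
        means, outcome,
    )


def fit_ols(data: MediationDataset, outcome: str, predictors: list[str]) -> PathFit:
    """OLS fit for cross-sectional (one record per subject) data.

    Classical standard errors; ``tau_sq_hat`` is fixed at 0 because the
    between/within decomposition is unidentified with a single measure.
    """
    if data.n_measures != 1:
        raise ValueError(
            "repeated measures present; use fit_random_intercept for m >= 2"
        )
    pred_idx, out_idx = _resolve_names(outcome, predictors)
    xc, mc, yc, means = _centered_columns(data)
    T, _ = subject_crossprods(xc, mc, yc)
    T4 = T.sum(axis=0)[None]
    core = _ols_fit_core(T4, pred_idx, out_idx, data.n_obs)
    return _pathfit_from_core(
        core, predictors, data.n_subjects, data.n_obs, "ols", means, outcome,
        tau_sq=0.0,
    )


def fit_mediation(data: MediationDataset, reml: bool = False) -> MediationFit:
    """Fit both mediation paths and derive the indirect-effect estimate.

    a-path: M ~ X; b-path: Y ~ X + M (the coefficient on M is beta_b-hat and
    on X is beta_c_prime-hat).  Random-intercept ML (or REML) for m >= 2,
    OLS for m = 1.
    """
    if data.n_measures >= 2:
        a = fit_random_intercept(data, "m", ["x"], reml=reml)
        b = fit_random_intercept(data, "y", ["x", "m"], reml=reml)
    else:
        a = fit_ols(data, "m", ["x"])
        b = fit_ols(data, "y", ["x", "m"])
    return MediationFit(a_path=a, b_path=b)
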