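"""Interval-based tests of the mediation effect H0: beta_a * beta_b = 0.

Three confidence intervals for the indirect effect are provided:

* **Sobel**: ab_hat +/- z_{1-alpha/2} * sobel_se (first-order delta method,
  symmetric, assumes normality of the product estimator).
* **Distribution of the product**: critical values from the empirical
  distribution of a product of two independent normals centered at the
  standardized path estimates (z_a, z_b), obtained by seeded Monte Carlo;
  the resulting interval is asymmetric in general.
* **Percentile cases bootstrap**: resample J subjects with replacement,
  keeping each drawn subject's records intact (upper level only, the
  recommended scheme when the number of repeated measures is small), refit
  the mediation model on each resample, and take empirical percentiles
  (type-7 / linear interpolation) of the bootstrap ab estimates.

Each test rejects H0 at level alpha iff its 100(1-alpha)% interval excludes 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from ._seeds import STREAM_BOOTSTRAP, rng_from, seed_sequence
from .datagen import MediationDataset
from .estimation import (
    MediationFit,
    _ml_fit_cs,
    _ols_fit_core,
    fit_mediation,
    subject_crossprods,
)

_A_PRED, _A_OUT = (0, 1), 2  # M ~ 1 + X
_B_PRED, _B_OUT = (0, 1, 2), 3  # Y ~ 1 + X + M


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided confidence interval for the mediation effect."""

    lower: float
    upper: float
    level: float
    method: str  # "sobel" | "product" | "bootstrap"
    rejects_null: bool
    estimate: float | None = None
    unreliable: bool = False

    def __post_init__(self):
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def _make_interval(lower, upper, alpha, method, estimate, unreliable=False):
    return IntervalEstimate(
        lower=float(lower),
        upper=float(upper),
        level=1.0 - alpha,
        method=method,
        rejects_null=not (lower <= 0.0 <= upper),
        estimate=float(estimate),
        unreliable=unreliable,
    )


def _check_alpha(alpha):
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")


def sobel_ci(fit: MediationFit, alpha: float = 0.05) -> IntervalEstimate:
    """Delta-method (Sobel) confidence interval, symmetric about ab_hat."""
    _check_alpha(alpha)
    if fit.sobel_se == 0.0 and fit.ab_hat != 0.0:
        warnings.warn(
            "degenerate Sobel interval: zero standard error with nonzero estimate",
            RuntimeWarning,
        )
    z = sps.norm.ppf(1.0 - alpha / 2.0)
    half = z * fit.sobel_se
    return _make_interval(
        fit.ab_hat - half, fit.ab_hat + half, alpha, "sobel", fit.ab_hat
    )


def product_critical_values(
    z_a: float,
    z_b: float,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Monte-Carlo critical values of the product-of-normals distribution.

    Draws (Z1, Z2) independent N(z_a, 1) and N(z_b, 1), forms P = Z1*Z2 and
    returns ``(delta_lower, delta_upper)``: the distances from the center
    z_a*z_b to the empirical alpha/2 and 1-alpha/2 quantiles of P,
    standardized by the exact standard deviation of the product,
    sd(P) = sqrt(z_a^2 + z_b^2 + 1).  These standardized critical values
    approach z_{1-alpha/2} in the large-|z| normal limit and rebuild the CI
    on the ab scale as (ab - delta_lower*se, ab + delta_upper*se) with the
    delta-method se.  Deterministic given seed.
    """
    _check_alpha(alpha)
    if n_mc < 1000:
        warnings.warn(
            f"n_mc={n_mc} gives imprecise critical values; use >= 1e5", RuntimeWarning
        )
    rng = np.random.default_rng(
        seed if isinstance(seed, np.random.SeedSequence) else int(seed)
    )
    p = (z_a + rng.standard_normal(n_mc)) * (z_b + rng.standard_normal(n_mc))
    q_lo, q_hi = np.quantile(p, [alpha / 2.0, 1.0 - alpha / 2.0])
    center = z_a * z_b
    sd = math.sqrt(z_a**2 + z_b**2 + 1.0)
    return float((center - q_lo) / sd), float((q_hi - center) / sd)


class ProductCritCache:
    """Critical values cached on (z_a, z_b) rounded to 2 decimals.

    Quantile Monte-Carlo error at 1e5 draws is far below power-table
    resolution, and rounding the standardized estimates to 0.01 changes the
    deltas negligibly, so repeated fits with similar z-scores share one draw.
    The Monte-Carlo seed for each cache key derives deterministically from
    the base seed and the rounded key, independent of evaluation order.
    """

    def __init__(self, alpha: float = 0.05, n_mc: int = 100_000, base_seed: int = 0):
        _check_alpha(alpha)
        self.alpha = alpha
        self.n_mc = n_mc
        self.base_seed = int(base_seed)
        self._cache: dict[tuple[int, int], tuple[float, float]] = {}

    def get(self, z_a: float, z_b: float) -> tuple[float, float]:
        ka = int(round(z_a * 100.0))
        kb = int(round(z_b * 100.0))
        key = (ka, kb)
        hit = self._cache.get(key)
        if hit is None:
            ss = seed_sequence(
                self.base_seed, 3, ka, kb, int(self.alpha * 1e6), self.n_mc
            )
            hit = product_critical_values(
                ka / 100.0, kb / 100.0, self.alpha, self.n_mc, seed=ss
            )
            self._cache[key] = hit
        return hit


def product_ci(
    fit: MediationFit,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int = 0,
) -> IntervalEstimate:
    """Distribution-of-the-product confidence interval for the indirect effect.

    Interval = (ab - delta_lower*se, ab + delta_upper*se) with the deltas
    from :func:`product_critical_values` at the fit's standardized estimates.
    """
    _check_alpha(alpha)
    if fit.sobel_se == 0.0:
        if fit.ab_hat != 0.0:
            warnings.warn(
                "degenerate product interval: zero standard error with nonzero "
                "estimate",
                RuntimeWarning,
            )
        return _make_interval(fit.ab_hat, fit.ab_hat, alpha, "product", fit.ab_hat)
    d_lo, d_hi = product_critical_values(fit.z_a, fit.z_b, alpha, n_mc, seed)
    return _make_interval(
        fit.ab_hat - d_lo * fit.sobel_se,
        fit.ab_hat + d_hi * fit.sobel_se,
        alpha,
        "product",
        fit.ab_hat,
    )


def percentile_interval(values: np.ndarray, alpha: float) -> tuple[float, float]:
    """Equal-tail empirical percentile interval, type-7 (linear) interpolation."""
    q = np.quantile(np.asarray(values, float), [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(q[0]), float(q[1])


def _bootstrap_ab_values(
    data: MediationDataset, B: int, rng: np.random.Generator,
    resample_lower: bool = False,
) -> np.ndarray:
    """ab_hat for B cases-bootstrap resamples (vectorized across resamples)."""
    J, mm = data.n_subjects, data.n_measures
    # centering on the original grand means: slopes are shift-invariant, and
    # near-centered columns keep the resampled cross-products well conditioned
    xc = data.x - data.x.mean()
    mc = data.m - data.m.mean()
    yc = data.y - data.y.mean()
    idx = rng.integers(0, J, size=(B, J))
    if resample_lower and mm > 1:
        # both-levels variant: also resample occasions within each drawn subject
        ridx = rng.integers(0, mm, size=(B, J, mm))
        xb = xc[idx[..., None], ridx]
        mb = mc[idx[..., None], ridx]
        yb = yc[idx[..., None], ridx]
        T, Bb = subject_crossprods(xb, mb, yb)
        T4 = T.sum(axis=1)
        B4 = Bb.sum(axis=1)
    else:
        T, Bb = subject_crossprods(xc, mc, yc)
        T4 = T[idx].sum(axis=1)
        B4 = Bb[idx].sum(axis=1)
    if mm == 1:
        a = _ols_fit_core(T4, _A_PRED, _A_OUT, J)
        b = _ols_fit_core(T4, _B_PRED, _B_OUT, J)
    else:
        W4 = T4 - B4
        a = _ml_fit_cs(W4, B4, _A_PRED, _A_OUT, J, mm)
        b = _ml_fit_cs(W4, B4, _B_PRED, _B_OUT, J, mm)
    ab = a["beta"][:, 1] * b["beta"][:, 2]
    ab[~(a["ok"] & b["ok"])] = np.nan
    return ab


def bootstrap_ci(
    data: MediationDataset,
    alpha: float = 0.05,
    B: int = 500,
    seed: int = 0,
    resample_lower: bool = False,
) -> IntervalEstimate:
    """Percentile cases-bootstrap confidence interval for the indirect effect.

    Resamples J subject ids with replacement and copies each drawn subject's
    complete set of records intact; resampled subjects act as distinct groups,
    so every bootstrap likelihood has J groups.  ``resample_lower=True``
    additionally resamples occasions within subjects (off by default).
    Deterministic given seed.  If more than 20% of bootstrap fits fail, the
    interval is flagged ``unreliable``.
    """
    _check_alpha(alpha)
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(
            f"B={B} bootstrap samples give imprecise percentiles", RuntimeWarning
        )
    rng = rng_from(seed, STREAM_BOOTSTRAP)
    ab = _bootstrap_ab_values(data, B, rng, resample_lower=resample_lower)
    good = ab[np.isfinite(ab)]
    n_failed = B - good.size
    unreliable = n_failed > 0.2 * B
    if unreliable:
        warnings.warn(
            f"{n_failed}/{B} bootstrap fits failed; interval flagged unreliable",
            RuntimeWarning,
        )
    if good.size == 0:
        raise RuntimeError("all bootstrap fits failed")
    lo, hi = percentile_interval(good, alpha)
    point = fit_mediation(data).ab_hat
    return _make_interval(lo, hi, alpha, "bootstrap", point, unreliable=unreliable)
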