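"""Monte-Carlo power, type-I error and sample-size search.

Power for a configuration and test method is the proportion of simulated
replicate datasets whose confidence interval for the indirect effect excludes
zero.  Replicates are simulated and fitted in vectorized batches (the
balanced compound-symmetry likelihood reduces every fit to small-matrix
algebra on per-subject cross-products), which keeps full-scale runs -- 1000
replicates, and 300 x 300 bootstrap refits -- to seconds rather than hours.

The sample-size search brackets the target power by doubling/halving from a
closed-form Sobel-approximation initial guess, then bisects on integers until
the bracket is adjacent, and returns the bracketing n whose estimated power is
nearest the target (ties to the smaller n).  Replicate seeds are shared across
candidate n within one search (common random numbers), so the search is fully
deterministic given the master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._seeds import STREAM_BOOTSTRAP, STREAM_DATASET, rng_from
from .config import SimulationConfig
from .datagen import MediationDataset, _simulate_arrays
from .estimation import _ml_fit_cs, _ols_fit_core, subject_crossprods
from .intervals import ProductCritCache, _bootstrap_ab_values, percentile_interval

logger = logging.getLogger(__name__)

METHODS = ("sobel", "product", "bootstrap")

_A_PRED, _A_OUT = (0, 1), 2
_B_PRED, _B_OUT = (0, 1, 2), 3


@dataclass
class PowerEstimate:
    """Monte-Carlo rejection proportion with its binomial standard error."""

    power: float
    n_reps_used: int
    n_dropped: int
    mc_se: float
    config: SimulationConfig
    method: str
    alpha: float


@dataclass
class SampleSizeResult:
    """Smallest number of subjects attaining the target power.

    ``trace`` is the full evaluation history [(n, power), ...] in the order
    visited by the search, for auditability.
    """

    n_required: int
    achieved_power: float
    target_power: float
    trace: list[tuple[int, float]] = field(default_factory=list)
    method: str = "product"
    n_reps: int = 1000
    seed: int = 0


def _simulate_batch(config: SimulationConfig, rep_indices, seed):
    """Stack per-replicate simulated arrays; replicate r uses its own RNG
    derived from (seed, STREAM_DATASET, r), so any replicate can be
    regenerated in isolation and batching does not change the draws."""
    xs, ms, ys = [], [], []
    for r in rep_indices:
        rng = rng_from(seed, STREAM_DATASET, int(r))
        x, m, y = _simulate_arrays(config, rng)
        xs.append(x)
        ms.append(m)
        ys.append(y)
    return np.stack(xs), np.stack(ms), np.stack(ys)


def _fit_paths_batch(x, m, y, mm):
    """Batched a-path and b-path fits; returns (ab, sobel_se, z_a, z_b, ok)."""
    J = x.shape[1]
    # per-replicate grand-mean centering: slopes are shift-invariant and the
    # centered cross-products avoid cancellation
    x = x - x.mean(axis=(1, 2), keepdims=True)
    m = m - m.mean(axis=(1, 2), keepdims=True)
    y = y - y.mean(axis=(1, 2), keepdims=True)
    T, B = subject_crossprods(x, m, y)
    if mm == 1:
        T4 = T.sum(axis=1)
        a = _ols_fit_core(T4, _A_PRED, _A_OUT, J)
        b = _ols_fit_core(T4, _B_PRED, _B_OUT, J)
    else:
        W4 = (T - B).sum(axis=1)
        B4 = B.sum(axis=1)
        a = _ml_fit_cs(W4, B4, _A_PRED, _A_OUT, J, mm)
        b = _ml_fit_cs(W4, B4, _B_PRED, _B_OUT, J, mm)
    ahat, se_a = a["beta"][:, 1], a["se"][:, 1]
    bhat, se_b = b["beta"][:, 2], b["se"][:, 2]
    ab = ahat * bhat
    sobel_se = np.sqrt(se_a**2 * bhat**2 + se_b**2 * ahat**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_a = np.where(se_a > 0, ahat / se_a, np.inf)
        z_b = np.where(se_b > 0, bhat / se_b, np.inf)
    ok = a["ok"] & b["ok"] & np.isfinite(sobel_se) & (sobel_se > 0)
    return ab, sobel_se, z_a, z_b, ok


def estimate_power(
    config: SimulationConfig,
    method: str = "product",
    n_reps: int = 1000,
    alpha: float = 0.05,
    boot_B: int = 500,
    seed: int | None = None,
    n_mc: int = 100_000,
    crit_cache: ProductCritCache | None = None,
) -> PowerEstimate:
    """Monte-Carlo power of one mediation test at the given configuration.

    Simulates ``n_reps`` datasets, applies the chosen test at level ``alpha``
    to each, and returns the rejection proportion among converged replicates.
    Replicate sub-seeds derive deterministically from ``seed`` (default:
    ``config.seed``).
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if config.n_subjects is None:
        raise ValueError("config.n_subjects must be set; use find_sample_size to search")
    seed = config.seed if seed is None else int(seed)
    mm = config.n_measures
    J = config.n_subjects

    rejected = 0
    used = 0
    if method == "bootstrap":
        for r in range(n_reps):
            rng = rng_from(seed, STREAM_DATASET, r)
            x, m, y = _simulate_arrays(config, rng)
            data = MediationDataset(x=x, m=m, y=y)
            brng = rng_from(seed, STREAM_BOOTSTRAP, r)
            ab = _bootstrap_ab_values(data, boot_B, brng)
            good = ab[np.isfinite(ab)]
            if good.size < 0.8 * boot_B:
                continue  # unreliable replicate, dropped from the denominator
            lo, hi = percentile_interval(good, alpha)
            used += 1
            rejected += int(not (lo <= 0.0 <= hi))
            if (r + 1) % 100 == 0:
                logger.info("bootstrap power: replicate %d/%d", r + 1, n_reps)
    else:
        if crit_cache is None and method == "product":
            crit_cache = ProductCritCache(alpha=alpha, n_mc=n_mc, base_seed=seed)
        z_crit = sps.norm.ppf(1.0 - alpha / 2.0)
        chunk = max(1, min(512, int(2_000_000 // max(J * mm, 1))))
        for start in range(0, n_reps, chunk):
            reps = range(start, min(start + chunk, n_reps))
            x, m, y = _simulate_batch(config, reps, seed)
            ab, se, z_a, z_b, ok = _fit_paths_batch(x, m, y, mm)
            ab, se, z_a, z_b = ab[ok], se[ok], z_a[ok], z_b[ok]
            if method == "sobel":
                rej = np.abs(ab) > z_crit * se
            else:
                rej = np.empty(ab.size, dtype=bool)
                for i in range(ab.size):
                    d_lo, d_hi = crit_cache.get(z_a[i], z_b[i])
                    rej[i] = (ab[i] - d_lo * se[i] > 0.0) or (ab[i] + d_hi * se[i] < 0.0)
            used += int(ok.sum())
            rejected += int(rej.sum())
            logger.debug("power: %d/%d replicates done", min(start + chunk, n_reps), n_reps)

    power = rejected / used if used else float("nan")
    mc_se = float(np.sqrt(power * (1.0 - power) / used)) if used else float("nan")
    return PowerEstimate(
        power=power,
        n_reps_used=used,
        n_dropped=n_reps - used,
        mc_se=mc_se,
        config=config,
        method=method,
        alpha=alpha,
    )


def estimate_type1_error(
    config: SimulationConfig,
    method: str = "product",
    n_reps: int = 1000,
    alpha: float = 0.05,
    boot_B: int = 500,
    seed: int | None = None,
    **kwargs,
) -> PowerEstimate:
    """Rejection rate under H0 (at least one of beta_a, beta_b equal to 0).

    Identical machinery to :func:`estimate_power`; refuses configurations
    with both effects nonzero, because those measure power, not type-I error.
    """
    if config.beta_a * config.beta_b != 0.0:
        raise ValueError(
            "type-I error requires beta_a*beta_b == 0; got nonzero effects "
            f"(beta_a={config.beta_a}, beta_b={config.beta_b}) -- use estimate_power"
        )
    return estimate_power(
        config, method=method, n_reps=n_reps, alpha=alpha, boot_B=boot_B,
        seed=seed, **kwargs,
    )


def sobel_sample_size_guess(
    config: SimulationConfig,
    alpha: float = 0.05,
    target_power: float = 0.8,
) -> int:
    """Closed-form initial guess from the Sobel normal approximation.

    Uses large-sample per-subject Fisher information for the two slopes under
    the generative model.  For subject-constant X the a-path is a
    between-subject regression with residual variance tau^2 + sigma^2/m; for
    time-varying X, E[x' V^{-1} x] = (m-1)/lambda_2 + 1/lambda_1 per subject.
    The b-path predictor residual (M given X) has within variance sigma^2 and
    between variance tau^2, giving information exactly m per subject under
    the shared-variance parameterization.  Solves
    (z_{1-a/2} + z_pow)^2 (v_a b^2 + v_b a^2) / (ab)^2 for J.  The normal
    approximation is crude (the product estimator is skewed), so this is only
    a bracketing start, not an answer.
    """
    tau2, sig2 = config.tau_sq, config.sigma_sq
    mm = config.n_measures
    lam1 = sig2 + mm * tau2
    if mm == 1:
        v_a = v_b = tau2 + sig2
    else:
        if config.x_mode == "subject_constant":
            info_a = 1.0 / (tau2 + sig2 / mm)
        else:
            info_a = (mm - 1) / sig2 + 1.0 / lam1
        info_b = sig2 * ((mm - 1) / sig2 + 1.0 / lam1) + mm * tau2 / lam1
        v_a, v_b = 1.0 / info_a, 1.0 / info_b
    zq = sps.norm.ppf(1.0 - alpha / 2.0) + sps.norm.ppf(target_power)
    ab_sq = (config.beta_a * config.beta_b) ** 2
    j = zq**2 * (v_a * config.beta_b**2 + v_b * config.beta_a**2) / ab_sq
    return max(3, int(np.ceil(j)))


def find_sample_size(
    config: SimulationConfig,
    method: str = "product",
    target_power: float = 0.80,
    n_reps: int = 1000,
    alpha: float = 0.05,
    boot_B: int = 500,
    seed: int | None = None,
    n_min: int = 3,
    n_max: int = 1_000_000,
    **power_kwargs,
) -> SampleSizeResult:
    """Search for the smallest J reaching the target power.

    ``config.n_subjects`` is ignored (it is the unknown).  Bracket by
    doubling/halving from the Sobel-approximation guess, bisect on integers,
    then return the bracketing n whose power is nearest the target (ties to
    the smaller n).  Common random numbers across candidate n reduce search
    noise; the whole search is deterministic given the master seed.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError("target_power must lie in (0, 1)")
    if config.beta_a * config.beta_b == 0.0:
        raise ValueError("sample-size search requires nonzero beta_a and beta_b")
    seed = config.seed if seed is None else int(seed)

    evaluated: dict[int, float] = {}
    trace: list[tuple[int, float]] = []

    def power_at(n: int) -> float:
        if n not in evaluated:
            cfg = config.replace(n_subjects=int(n))
            est = estimate_power(
                cfg, method=method, n_reps=n_reps, alpha=alpha, boot_B=boot_B,
                seed=seed, **power_kwargs,
            )
            evaluated[n] = est.power
            trace.append((int(n), est.power))
            logger.info("sample-size search: n=%d power=%.4f", n, est.power)
        return evaluated[n]

    n0 = sobel_sample_size_guess(config, alpha, target_power)
    n0 = int(np.clip(n0, n_min, n_max))

    # bracket: lo has power < target <= power at hi
    if power_at(n0) >= target_power:
        hi = n0
        lo = n0
        while lo > n_min:
            lo = max(n_min, lo // 2)
            if power_at(lo) < target_power:
                break
            hi = lo
        else:
            pass
        if power_at(lo) >= target_power:
            return SampleSizeResult(
                n_required=lo, achieved_power=power_at(lo),
                target_power=target_power, trace=trace, method=method,
                n_reps=n_reps, seed=seed,
            )
    else:
        lo = n0
        hi = n0
        while hi < n_max:
            hi = min(n_max, hi * 2)
            if power_at(hi) >= target_power:
                break
            lo = hi
        if power_at(hi) < target_power:
            raise RuntimeError(
                f"target power {target_power} not bracketable in [{n_min}, {n_max}]: "
                f"power({n_min if lo == n_min else lo})={power_at(lo):.3f}, "
                f"power({hi})={power_at(hi):.3f}"
            )

    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power_at(mid) >= target_power:
            hi = mid
        else:
            lo = mid

    # "nearest to target": the bracketing integer whose power is closest to
    # the target; ties go to the smaller n
    p_lo, p_hi = power_at(lo), power_at(hi)
    if abs(p_lo - target_power) <= abs(p_hi - target_power):
        n_req, p_req = lo, p_lo
    else:
        n_req, p_req = hi, p_hi
    return SampleSizeResult(
        n_required=int(n_req), achieved_power=float(p_req),
        target_power=target_power, trace=trace, method=method,
        n_reps=n_reps, seed=seed,
    )
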