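"""Simulation configuration for the two-level (1-1-1) mediation model.

The generative model has a lower (measurement) level and an upper (subject)
level.  For subject j = 1..J and measurement occasion i = 1..m:

    M_ij = gamma_3 + u3_j + beta_a * X_ij + e3_ij
    Y_ij = gamma_2 + u2_j + beta_c_prime * X_ij + beta_b * M_ij + e2_ij

with u2_j ~ N(0, tau2_sq), u3_j ~ N(0, tau3_sq) drawn once per subject and
e2_ij ~ N(0, sigma2_sq), e3_ij ~ N(0, sigma3_sq) drawn per occasion.  Both
equations share one within-subject correlation parameter ``icc`` that sets
tau2_sq = tau3_sq = icc; the within-subject variance is either fixed at 1
("unit_within", the convention the published sample-size tables encode) or
at 1 - icc ("unit_marginal", which makes tau^2 + sigma^2 = 1 so the error
intraclass correlation is exactly icc).  The normalization applies to the
error components of each equation, not to Var(Y): with nonzero beta_b,
Var(Y) exceeds the error variance by construction.

``n_measures = 1`` selects the cross-sectional special case (single-level
mediation, estimated by OLS downstream).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


class ConfigError(ValueError):
    """A configuration field violates its constraints; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


X_MODES = ("subject_constant", "iid_standard_normal")
VARIANCE_MODES = ("unit_within", "unit_marginal")


@dataclass(frozen=True)
class SimulationConfig:
    """All generative parameters of the two-level mediation model.

    Parameters
    ----------
    beta_a : float
        X -> M path coefficient.
    beta_b : float
        M -> Y path coefficient, adjusted for X.
    beta_c_prime : float
        Direct X -> Y effect adjusted for M; conventionally 0 in power
        studies of the indirect effect.
    gamma_2, gamma_3 : float
        Population intercepts of the Y- and M-equations.
    icc : float
        Within-subject correlation parameter in [0, 1); sets the
        between-subject variance tau^2 = icc of both equations.  How the
        within-subject variance follows from it depends on
        ``variance_mode``.
    variance_mode : str
        "unit_within" (default): sigma^2 = 1, so repeated measures carry
        unit-variance occasion noise and tau^2 = icc is added on top of it
        (marginal correlation icc / (1 + icc)).  This is the convention
        under which the published sample-size tables for this design were
        computed, verified cell by cell against their power surface.
        "unit_marginal": sigma^2 = 1 - icc, enforcing tau^2 + sigma^2 = 1
        so that the intraclass correlation of the errors equals icc
        exactly.
    n_subjects : int or None
        Number of upper-level units J (None only for sample-size search,
        where J is the unknown).
    n_measures : int
        Repeated measures per subject m; 1 means single-level mode.
    x_mode : str
        Generative law for X_ij.  "subject_constant" (default) draws one
        standard-normal X per subject and repeats it across occasions, the
        randomized-treatment scenario whose power surface reproduces the
        published sample-size tables.  "iid_standard_normal" draws X fresh
        at every occasion (a time-varying exposure, e.g. cross-over).
    seed : int
        Master RNG seed; all downstream randomness derives from it.
    """

    beta_a: float
    beta_b: float
    beta_c_prime: float = 0.0
    gamma_2: float = 0.0
    gamma_3: float = 0.0
    icc: float = 0.0
    n_subjects: int | None = None
    n_measures: int = 1
    x_mode: str = "subject_constant"
    variance_mode: str = "unit_within"
    seed: int = 0

    def __post_init__(self):
        for name in ("beta_a", "beta_b", "beta_c_prime", "gamma_2", "gamma_3"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or not math.isfinite(v):
                raise ConfigError(name, f"must be a finite real, got {v!r}")
        if not isinstance(self.icc, (int, float)) or not (0.0 <= self.icc < 1.0):
            raise ConfigError("icc", f"must lie in [0, 1), got {self.icc!r}")
        if self.n_subjects is not None:
            if not isinstance(self.n_subjects, int) or self.n_subjects < 1:
                raise ConfigError(
                    "n_subjects", f"must be a positive integer, got {self.n_subjects!r}"
                )
        if not isinstance(self.n_measures, int) or self.n_measures < 1:
            raise ConfigError(
                "n_measures", f"must be a positive integer, got {self.n_measures!r}"
            )
        if self.x_mode not in X_MODES:
            raise ConfigError("x_mode", f"must be one of {X_MODES}, got {self.x_mode!r}")
        if self.variance_mode not in VARIANCE_MODES:
            raise ConfigError(
                "variance_mode",
                f"must be one of {VARIANCE_MODES}, got {self.variance_mode!r}",
            )
        if not isinstance(self.seed, int):
            raise ConfigError("seed", f"must be an integer, got {self.seed!r}")

    # variance components implied by the ICC normalization
    @property
    def tau_sq(self) -> float:
        """Between-subject variance tau^2 (= icc) of both equations."""
        return float(self.icc)

    @property
    def sigma_sq(self) -> float:
        """Within-subject error variance sigma^2 of both equations."""
        return 1.0 if self.variance_mode == "unit_within" else 1.0 - float(self.icc)

    @property
    def error_icc(self) -> float:
        """Intraclass correlation of the error process, tau^2/(tau^2+sigma^2)."""
        t, s = self.tau_sq, self.sigma_sq
        return t / (t + s)

    @property
    def single_level(self) -> bool:
        return self.n_measures == 1

    def replace(self, **kwargs) -> "SimulationConfig":
        """A copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **kwargs)
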