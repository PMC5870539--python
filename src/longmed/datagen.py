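"""Synthetic data generation for the two-level mediation model.

Datasets are balanced: J subjects, each with exactly m measurement occasions,
no missing values.  X is standard normal, drawn once per subject (default,
the randomized-treatment scenario) or fresh at every occasion; random
intercepts are drawn once per subject, and M and Y follow the
random-intercept equations described in :mod:`longmed.config`.

The in-memory container :class:`MediationDataset` stores the three variables
as (J, m) arrays for speed and converts to/from a long-format pandas frame
(columns ``subject, measure, x, m, y``) for user-facing I/O.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import STREAM_DATASET, rng_from
from .config import ConfigError, SimulationConfig

CSV_COLUMNS = ("subject", "measure", "x", "m", "y")


@dataclass(frozen=True)
class MediationDataset:
    """Balanced long-format mediation data (subject x occasion x {x, m, y}).

    Arrays have shape (n_subjects, n_measures); row j holds subject j+1.
    """

    x: np.ndarray
    m: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        for name in ("x", "m", "y"):
            a = getattr(self, name)
            if a.ndim != 2:
                raise ValueError(f"{name} must be 2-d (subjects x measures)")
            if a.shape != self.x.shape:
                raise ValueError("x, m, y must share one (subjects, measures) shape")
            if not np.all(np.isfinite(a)):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def n_measures(self) -> int:
        return self.x.shape[1]

    @property
    def n_obs(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        """Long-format records with 1-based contiguous subject/measure ids."""
        J, m = self.x.shape
        return pd.DataFrame(
            {
                "subject": np.repeat(np.arange(1, J + 1), m),
                "measure": np.tile(np.arange(1, m + 1), J),
                "x": self.x.ravel(),
                "m": self.m.ravel(),
                "y": self.y.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MediationDataset":
        """Build from a long-format frame; enforces the balanced design."""
        missing = [c for c in CSV_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        df = frame.sort_values(["subject", "measure"], kind="stable")
        subjects = df["subject"].to_numpy()
        uniq, counts = np.unique(subjects, return_counts=True)
        if not np.array_equal(uniq, np.arange(1, len(uniq) + 1)):
            raise ValueError("subject ids must be contiguous integers 1..J")
        if counts.min() != counts.max():
            raise ValueError("unbalanced design: subjects differ in record counts")
        m = int(counts[0])
        J = len(uniq)
        shape = (J, m)
        return cls(
            x=df["x"].to_numpy(dtype=float).reshape(shape),
            m=df["m"].to_numpy(dtype=float).reshape(shape),
            y=df["y"].to_numpy(dtype=float).reshape(shape),
        )

    def write_csv(self, path) -> None:
        """Write long-format CSV, lossless to full double precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "MediationDataset":
        # round_trip parsing: the default fast float parser can be 1 ulp off
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))


def _simulate_arrays(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (x, m, y) arrays of shape (J, m) from the two-level model."""
    J, mm = config.n_subjects, config.n_measures
    tau = np.sqrt(config.tau_sq)
    sig = np.sqrt(config.sigma_sq)
    # one between-subject error per subject and equation
    u2 = rng.normal(0.0, tau, size=J) if tau > 0 else np.zeros(J)
    u3 = rng.normal(0.0, tau, size=J) if tau > 0 else np.zeros(J)
    if config.x_mode == "subject_constant":
        x = np.repeat(rng.standard_normal(size=(J, 1)), mm, axis=1)
    else:
        x = rng.standard_normal(size=(J, mm))
    e3 = rng.normal(0.0, sig, size=(J, mm))
    e2 = rng.normal(0.0, sig, size=(J, mm))
    m = config.gamma_3 + u3[:, None] + config.beta_a * x + e3
    y = config.gamma_2 + u2[:, None] + config.beta_c_prime * x + config.beta_b * m + e2
    return x, m, y


def simulate_dataset(config: SimulationConfig, replicate: int = 0) -> MediationDataset:
    """Simulate one balanced dataset from the two-level mediation model.

    Parameters
    ----------
    config : SimulationConfig
        Generative parameters; ``n_subjects`` must be set.
    replicate : int
        Replicate counter.  Monte-Carlo drivers pass 0, 1, 2, ...; replicate
        r of a run is bit-identical to ``simulate_dataset(config, r)``.

    Returns
    -------
    MediationDataset
        Identical (config, replicate) always yields a bit-identical dataset.
    """
    if config.n_subjects is None:
        raise ConfigError("n_subjects", "must be set to simulate a dataset")
    rng = rng_from(config.seed, STREAM_DATASET, replicate)
    x, m, y = _simulate_arrays(config, rng)
    return MediationDataset(x=x, m=m, y=y)
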