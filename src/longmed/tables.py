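"""Batch reproduction of the factorial sample-size study, plus config I/O.

The study grid crosses effect-size cells (two letters: the first is beta_a,
the second beta_b, from the label map S=0.14, H=0.26, M=0.39, L=0.59, with Z=0
reserved for type-I-error scenarios) with ICC values, numbers of repeated
measures and test methods.  :func:`run_grid` runs the sample-size search for
every combination and emits a long-format CSV plus a wide table mirroring the
conventional layout (rows = effect cells, columns = m x method at one ICC).

Two profiles are provided: ``full`` (1000 replicates, 500 bootstrap samples)
for reference-scale runs and ``smoke`` (300 / 300) for quick runs, whose
wider Monte-Carlo error is absorbed by correspondingly wider tolerance bands.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .config import ConfigError, SimulationConfig
from .power import METHODS, estimate_type1_error, find_sample_size

logger = logging.getLogger(__name__)

#: Effect-size label map; Z marks a null path for type-I-error scenarios.
EFFECT_SIZES = {"S": 0.14, "H": 0.26, "M": 0.39, "L": 0.59, "Z": 0.0}

PROFILES = {
    "full": {"n_reps": 1000, "boot_B": 500},
    "smoke": {"n_reps": 300, "boot_B": 300},
}

LONG_COLUMNS = (
    "effect_a",
    "effect_b",
    "icc",
    "m",
    "method",
    "n_required",
    "achieved_power",
    "mc_se",
    "seed",
)


def parse_cell(cell: str) -> tuple[float, float]:
    """Map a two-letter effect cell like 'SM' to (beta_a, beta_b)."""
    if len(cell) != 2 or cell[0] not in EFFECT_SIZES or cell[1] not in EFFECT_SIZES:
        raise ValueError(
            f"effect cell must be two letters from {sorted(EFFECT_SIZES)}, got {cell!r}"
        )
    return EFFECT_SIZES[cell[0]], EFFECT_SIZES[cell[1]]


def _cell_seed(seed: int, cell: str, icc: float, m: int, method: str) -> int:
    """A stable 31-bit per-cell seed so any row can be regenerated alone."""
    key = f"{seed}|{cell}|{icc:.6f}|{m}|{method}".encode()
    return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") & 0x7FFFFFFF


def _cache_path(cache_dir: Path, row_key: dict) -> Path:
    digest = hashlib.sha256(
        json.dumps(row_key, sort_keys=True).encode()
    ).hexdigest()[:16]
    return cache_dir / f"cell_{digest}.json"


def run_grid(
    cells: list[str],
    icc_list: list[float],
    m_list: list[int],
    methods: list[str] = ("sobel", "product", "bootstrap"),
    n_reps: int = 1000,
    boot_B: int = 500,
    alpha: float = 0.05,
    target_power: float = 0.80,
    seed: int = 0,
    cache_dir=None,
) -> pd.DataFrame:
    """Sample-size search for every (cell, icc, m, method) combination.

    All cells must have nonzero effects (a Z letter marks a null path and
    belongs to type-I-error runs, not power runs).  Returns a long-format
    DataFrame with one row per combination; every row carries the seed that
    regenerates it in isolation.  With ``cache_dir`` set, finished cells are
    stored as JSON and re-used on re-runs (corrupt entries are rebuilt with a
    warning).
    """
    for cell in cells:
        a, b = parse_cell(cell)
        if a == 0.0 or b == 0.0:
            raise ValueError(
                f"cell {cell!r} has a zero path; sample-size search needs nonzero "
                "effects -- use estimate_type1_error / run_type1_grid for Z cells"
            )
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        cache_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for cell in cells:
        beta_a, beta_b = parse_cell(cell)
        for icc in icc_list:
            for m in m_list:
                for method in methods:
                    cseed = _cell_seed(seed, cell, icc, m, method)
                    row_key = {
                        "cell": cell, "icc": icc, "m": m, "method": method,
                        "n_reps": n_reps, "boot_B": boot_B, "alpha": alpha,
                        "target_power": target_power, "seed": cseed,
                    }
                    row = None
                    if cache_dir is not None:
                        path = _cache_path(cache_dir, row_key)
                        if path.exists():
                            try:
                                cached = json.loads(path.read_text())
                                if cached["key"] == row_key:
                                    row = cached["row"]
                            except (json.JSONDecodeError, KeyError):
                                warnings.warn(
                                    f"corrupt cache entry {path.name}; rebuilding",
                                    RuntimeWarning,
                                )
                    if row is None:
                        cfg = SimulationConfig(
                            beta_a=beta_a, beta_b=beta_b, icc=icc,
                            n_measures=m, seed=cseed,
                        )
                        res = find_sample_size(
                            cfg, method=method, target_power=target_power,
                            n_reps=n_reps, alpha=alpha, boot_B=boot_B, seed=cseed,
                        )
                        p = res.achieved_power
                        row = {
                            "effect_a": cell[0], "effect_b": cell[1],
                            "icc": icc, "m": m, "method": method,
                            "n_required": res.n_required,
                            "achieved_power": p,
                            "mc_se": (p * (1.0 - p) / n_reps) ** 0.5,
                            "seed": cseed,
                        }
                        if cache_dir is not None:
                            _cache_path(cache_dir, row_key).write_text(
                                json.dumps({"key": row_key, "row": row})
                            )
                    logger.info(
                        "grid cell %s icc=%.2f m=%d %s -> n=%d",
                        cell, icc, m, method, row["n_required"],
                    )
                    rows.append(row)
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def run_type1_grid(
    cells: list[str],
    icc: float,
    m: int,
    methods: list[str],
    n_subjects_list: list[int],
    n_reps: int = 1000,
    boot_B: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Type-I-error rates over sample sizes for null cells (ZZ, ZL, LZ, ...)."""
    rows = []
    for cell in cells:
        beta_a, beta_b = parse_cell(cell)
        if beta_a != 0.0 and beta_b != 0.0:
            raise ValueError(f"cell {cell!r} has no zero path; this is a power run")
        for method in methods:
            for n in n_subjects_list:
                cseed = _cell_seed(seed, cell, icc, m, f"{method}@{n}")
                cfg = SimulationConfig(
                    beta_a=beta_a, beta_b=beta_b, icc=icc,
                    n_subjects=int(n), n_measures=m, seed=cseed,
                )
                est = estimate_type1_error(
                    cfg, method=method, n_reps=n_reps, alpha=alpha,
                    boot_B=boot_B, seed=cseed,
                )
                rows.append(
                    {
                        "cell": cell, "icc": icc, "m": m, "method": method,
                        "n_subjects": n, "rate": est.power, "mc_se": est.mc_se,
                        "seed": cseed,
                    }
                )
    return pd.DataFrame(rows)


def plot_type1_rates(frame: pd.DataFrame, ax=None):
    """Basic rejection-rate-vs-n plot for a type-I-error grid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (cell, method), grp in frame.groupby(["cell", "method"]):
        grp = grp.sort_values("n_subjects")
        ax.plot(grp["n_subjects"], grp["rate"], marker="o", label=f"{cell} {method}")
    ax.axhline(0.05, color="grey", linestyle="--", linewidth=0.8)
    ax.set_xlabel("number of subjects")
    ax.set_ylabel("rejection rate under H0")
    ax.legend(fontsize="small")
    return ax


def write_long_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.6g")


def to_wide(frame: pd.DataFrame, icc: float) -> pd.DataFrame:
    """Wide table for one ICC: rows = effect cells, columns = (m, method)."""
    sub = frame[frame["icc"] == icc].copy()
    sub["cell"] = sub["effect_a"] + sub["effect_b"]
    wide = sub.pivot_table(
        index="cell", columns=["m", "method"], values="n_required", aggfunc="first"
    )
    return wide


# ---------------------------------------------------------------------------
# flat key:value configuration files
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS = {
    "beta_c_prime": 0.0,
    "gamma_2": 0.0,
    "gamma_3": 0.0,
    "n_subjects": None,
    "alpha": 0.05,
    "method": "product",
    "reps": 1000,
    "boot_B": 500,
    "target_power": 0.80,
    "seed": 0,
    "x_mode": "subject_constant",
    "variance_mode": "unit_within",
}
_CONFIG_REQUIRED = ("beta_a", "beta_b", "icc", "n_measures")
_RUN_KEYS = ("alpha", "method", "reps", "boot_B", "target_power")


def load_config(path) -> dict:
    """Load and validate a flat YAML configuration file.

    Keys match the CLI flag names.  Returns the fully resolved configuration
    as a dict with a ``config`` entry (the :class:`SimulationConfig`) plus
    run options (alpha, method, reps, boot_B, target_power).  Unknown keys
    raise an error listing them; range violations name the offending field.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("file", f"{path} must contain a key: value mapping")
    known = set(_CONFIG_DEFAULTS) | set(_CONFIG_REQUIRED)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError("keys", f"unknown configuration keys: {unknown}")
    missing = [k for k in _CONFIG_REQUIRED if k not in raw]
    if missing:
        raise ConfigError("keys", f"missing required keys: {missing}")
    resolved = {**_CONFIG_DEFAULTS, **raw}
    if resolved["method"] not in METHODS:
        raise ConfigError("method", f"must be one of {METHODS}")
    if not 0.0 < resolved["alpha"] < 1.0:
        raise ConfigError("alpha", "must lie in (0, 1)")
    cfg = SimulationConfig(
        beta_a=float(resolved["beta_a"]),
        beta_b=float(resolved["beta_b"]),
        beta_c_prime=float(resolved["beta_c_prime"]),
        gamma_2=float(resolved["gamma_2"]),
        gamma_3=float(resolved["gamma_3"]),
        icc=float(resolved["icc"]),
        n_subjects=None if resolved["n_subjects"] is None else int(resolved["n_subjects"]),
        n_measures=int(resolved["n_measures"]),
        x_mode=resolved["x_mode"],
        variance_mode=resolved["variance_mode"],
        seed=int(resolved["seed"]),
    )
    return {"config": cfg, **{k: resolved[k] for k in _RUN_KEYS}}


def resolved_to_dict(resolved: dict) -> dict:
    """Flatten a resolved configuration back to the file representation."""
    cfg: SimulationConfig = resolved["config"]
    out = {
        "beta_a": cfg.beta_a,
        "beta_b": cfg.beta_b,
        "beta_c_prime": cfg.beta_c_prime,
        "gamma_2": cfg.gamma_2,
        "gamma_3": cfg.gamma_3,
        "icc": cfg.icc,
        "n_subjects": cfg.n_subjects,
        "n_measures": cfg.n_measures,
        "x_mode": cfg.x_mode,
        "variance_mode": cfg.variance_mode,
        "seed": cfg.seed,
    }
    out.update({k: resolved[k] for k in _RUN_KEYS})
    return out
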