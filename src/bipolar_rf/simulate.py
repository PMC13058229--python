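"""Synthetic ex vivo ablation cohorts.

Emulates a bench experiment in which bipolar RF energy is delivered across
porcine myocardial slices: slices of nominal thickness 10/15/20 mm are ablated
at 20–50 W for 20/60/180 s, and each application records the initial bipolar
impedance, the impedance drop over the first 5 s, an audible steam-pop flag and
a binary transmurality assessment.

Generative mechanism (all stages seeded from one NumPy generator):

1. thickness  = nominal level + Gaussian jitter (cutting tolerance);
2. impedance  = linear in thickness (two electrodes separated by more tissue
   see more resistance) + Gaussian noise;
3. 5-s impedance drop = linear in power and initial impedance + noise — higher
   power heats faster (more negative drop), higher baseline impedance shifts
   the drop upward on the absolute scale;
4. steam_pop  ~ Bernoulli(sigmoid) on (power, percent drop, thickness): pops
   favour high power, large early percentage drops and thin tissue;
5. a pop truncates delivery: actual duration ~ Uniform(5 s, planned);
6. transmural ~ Bernoulli(sigmoid) on (power, *actual* duration, impedance,
   thickness): thick tissue resists transmurality, dose helps.

Impedance drops are stored signed (negative = drop) throughout; the percentage
drop is drop x 100 / initial impedance, same sign.

Two designs are provided: ``grid`` crosses all thickness/power/duration levels
(the development experiment), and ``boundary_adjacent`` samples thin slices
with powers in a band around the Z = 1 steam-pop risk isopleth at a fixed 60-s
duration (the validation experiment, which deliberately courts pops).

Default coefficient values were calibrated once so that a large grid cohort
reproduces the marginal outcome rates of the bench study (about 49% transmural,
about 5.7% pops) and the ordering/location of the pop-vs-no-pop conditional
medians; they live here in config, not in code paths.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .boundary import BoundaryModel, boundary_power
from .errors import ConfigError, InvalidInputError
from .glm import sigmoid

#: canonical column order of a cohort table
COHORT_COLUMNS: tuple[str, ...] = (
    "cohort",
    "thickness",
    "rf_power",
    "rf_duration",
    "rf_duration_planned",
    "rf_duration_actual",
    "init_impedance",
    "imp_drop5",
    "pct_imp_drop5",
    "steam_pop",
    "transmural",
)


@dataclass(frozen=True)
class Drop5Coefficients:
    """Linear model of the signed 5-s impedance drop (ohms)."""

    intercept: float = -19.28
    per_watt: float = -0.15
    per_ohm: float = 0.20
    noise_sd: float = 1.5


@dataclass(frozen=True)
class PopCoefficients:
    """Logit coefficients of the steam-pop mechanism."""

    intercept: float = -8.60
    rf_power: float = 0.08
    pct_imp_drop5: float = -0.80
    thickness: float = -0.35


@dataclass(frozen=True)
class TransmuralCoefficients:
    """Logit coefficients of the transmurality mechanism (on actual duration)."""

    intercept: float = 12.15
    rf_power: float = 0.12
    rf_duration_actual: float = 0.02
    init_impedance: float = -0.05
    thickness: float = -0.90


@dataclass(frozen=True)
class GeneratorConfig:
    thickness_levels: tuple[float, ...] = (10.0, 15.0, 20.0)
    thickness_jitter_sd: float = 1.0
    power_levels: tuple[float, ...] = (20.0, 30.0, 40.0, 50.0)
    duration_levels: tuple[float, ...] = (20.0, 60.0, 180.0)
    impedance_intercept: float = 86.213122
    impedance_slope: float = 0.5057449
    impedance_noise_sd: float = 2.5
    drop5_coefficients: Drop5Coefficients = field(default_factory=Drop5Coefficients)
    pop_coefficients: PopCoefficients = field(default_factory=PopCoefficients)
    transmural_coefficients: TransmuralCoefficients = field(
        default_factory=TransmuralCoefficients
    )
    seed: int = 20260919
    design: str = "grid"
    # boundary_adjacent design: thin slices, powers in a band around the Z = 1
    # isopleth of `boundary_model`, duration pinned (validation protocol)
    boundary_thickness_range: tuple[float, float] = (8.0, 13.0)
    boundary_power_band: float = 4.0
    boundary_duration: float = 60.0
    boundary_model: BoundaryModel = field(default_factory=BoundaryModel)
    # a pop stops delivery somewhere in (pop_min_duration, planned)
    pop_min_duration: float = 5.0

    def __post_init__(self) -> None:
        for name in ("thickness_levels", "power_levels", "duration_levels"):
            levels = getattr(self, name)
            if len(levels) == 0:
                raise ConfigError(f"{name} must be non-empty")
            if any(v <= 0 for v in levels):
                raise ConfigError(f"{name} must be positive")
        for name in ("thickness_jitter_sd", "impedance_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.drop5_coefficients.noise_sd < 0:
            raise ConfigError("drop5 noise_sd must be >= 0")
        if self.design not in ("grid", "boundary_adjacent"):
            raise ConfigError(f"unknown design {self.design!r}")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_config_dict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        return _config_from_dict(yaml.safe_load(Path(path).read_text()))


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    for key in ("thickness_levels", "power_levels", "duration_levels",
                "boundary_thickness_range"):
        d[key] = list(d[key])
    return d


def _config_from_dict(d: Mapping) -> GeneratorConfig:
    d = dict(d)
    for key, typ in (
        ("drop5_coefficients", Drop5Coefficients),
        ("pop_coefficients", PopCoefficients),
        ("transmural_coefficients", TransmuralCoefficients),
        ("boundary_model", BoundaryModel),
    ):
        if key in d and isinstance(d[key], Mapping):
            d[key] = typ(**d[key])
    for key in ("thickness_levels", "power_levels", "duration_levels",
                "boundary_thickness_range"):
        if key in d:
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def impedance_from_thickness(
    thickness: float | np.ndarray,
    config: GeneratorConfig | None = None,
    *,
    rng: np.random.Generator | None = None,
) -> float | np.ndarray:
    """Initial bipolar impedance (ohms) implied by tissue thickness (mm).

    Deterministic linear relation ``intercept + slope * thickness``; Gaussian
    noise with sd ``config.impedance_noise_sd`` is added only when ``rng`` is
    supplied.  Non-positive thickness is rejected.
    """
    cfg = config or GeneratorConfig()
    t = np.asarray(thickness, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("thickness must be positive")
    z = cfg.impedance_intercept + cfg.impedance_slope * t
    if rng is not None and cfg.impedance_noise_sd > 0:
        z = z + rng.normal(0.0, cfg.impedance_noise_sd, size=t.shape)
    if np.isscalar(thickness) or np.ndim(thickness) == 0:
        return float(z)
    return z


def percent_imp_drop5(imp_drop5, init_impedance):
    """Signed percentage impedance drop: drop x 100 / initial impedance."""
    drop = np.asarray(imp_drop5, dtype=float)
    z0 = np.asarray(init_impedance, dtype=float)
    if np.any(z0 <= 0):
        raise InvalidInputError("init_impedance must be positive")
    pct = drop * 100.0 / z0
    if np.ndim(imp_drop5) == 0 and np.ndim(init_impedance) == 0:
        return float(pct)
    return pct


def _grid_conditions(cfg: GeneratorConfig, n_total: int | None,
                     n_per_cell: int | None) -> np.ndarray:
    cells = [
        (t, p, d)
        for t in cfg.thickness_levels
        for p in cfg.power_levels
        for d in cfg.duration_levels
    ]
    if n_per_cell is not None:
        rows = [c for c in cells for _ in range(n_per_cell)]
    else:
        # round-robin so any n_total spreads as evenly as possible
        rows = [cells[i % len(cells)] for i in range(n_total)]
    return np.array(rows, dtype=float).reshape(-1, 3)


def _boundary_conditions(cfg: GeneratorConfig, n_total: int,
                         rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.boundary_thickness_range
    t = rng.uniform(lo, hi, size=n_total)
    e_star = np.array([boundary_power(ti, cfg.boundary_model) for ti in t])
    e = e_star + rng.uniform(-cfg.boundary_power_band, cfg.boundary_power_band,
                             size=n_total)
    e = np.clip(e, min(cfg.power_levels), max(cfg.power_levels))
    d = np.full(n_total, cfg.boundary_duration)
    return np.column_stack([t, e, d])


def generate_cohort(
    config: GeneratorConfig | None = None,
    *,
    n_total: int | None = None,
    n_per_cell: int | None = None,
    cohort: str = "development",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a cohort of RF applications as a tidy DataFrame.

    Exactly one of ``n_total`` / ``n_per_cell`` must be given (the
    ``boundary_adjacent`` design takes only ``n_total``).  The result is fully
    reproducible from (config, seed, n): identical calls yield identical
    tables.
    """
    cfg = config or GeneratorConfig()
    if (n_total is None) == (n_per_cell is None):
        raise InvalidInputError("give exactly one of n_total / n_per_cell")
    if (n_total is not None and n_total < 0) or (
        n_per_cell is not None and n_per_cell < 0
    ):
        raise InvalidInputError("cohort size must be >= 0")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    if cfg.design == "grid":
        cond = _grid_conditions(cfg, n_total, n_per_cell)
    else:
        if n_per_cell is not None:
            raise ConfigError("boundary_adjacent design takes n_total only")
        cond = _boundary_conditions(cfg, n_total, rng)

    n = len(cond)
    if n == 0:
        return pd.DataFrame(columns=list(COHORT_COLUMNS))

    nominal_t, power, planned = cond[:, 0], cond[:, 1], cond[:, 2]
    thickness = nominal_t + rng.normal(0.0, cfg.thickness_jitter_sd, size=n)
    thickness = np.clip(thickness, 0.5, None)
    z0 = np.asarray(impedance_from_thickness(thickness, cfg, rng=rng))
    d5 = cfg.drop5_coefficients
    drop = (
        d5.intercept
        + d5.per_watt * power
        + d5.per_ohm * z0
        + rng.normal(0.0, d5.noise_sd, size=n)
    )
    pct = np.asarray(percent_imp_drop5(drop, z0))

    pc = cfg.pop_coefficients
    pop_logit = (
        pc.intercept
        + pc.rf_power * power
        + pc.pct_imp_drop5 * pct
        + pc.thickness * thickness
    )
    pop = (rng.uniform(size=n) < np.asarray(sigmoid(pop_logit))).astype(int)

    actual = planned.copy()
    stopped = pop == 1
    if stopped.any():
        lo = np.minimum(cfg.pop_min_duration, planned[stopped] * 0.5)
        actual[stopped] = rng.uniform(lo, planned[stopped])

    tc = cfg.transmural_coefficients
    trans_logit = (
        tc.intercept
        + tc.rf_power * power
        + tc.rf_duration_actual * actual
        + tc.init_impedance * z0
        + tc.thickness * thickness
    )
    trans = (rng.uniform(size=n) < np.asarray(sigmoid(trans_logit))).astype(int)

    return pd.DataFrame(
        {
            "cohort": cohort,
            "thickness": thickness,
            "rf_power": power,
            # rf_duration is the analysis predictor: the planned (set) duration
            "rf_duration": planned,
            "rf_duration_planned": planned,
            "rf_duration_actual": actual,
            "init_impedance": z0,
            "imp_drop5": drop,
            "pct_imp_drop5": pct,
            "steam_pop": pop,
            "transmural": trans,
        }
    )[list(COHORT_COLUMNS)]


def write_cohort(data: pd.DataFrame, path: str | Path,
                 config: GeneratorConfig | None = None,
                 seed: int | None = None) -> None:
    """Write a cohort CSV (fixed header) plus an adjacent .meta.json sidecar."""
    path = Path(path)
    # default float repr is shortest-round-trip: the CSV is lossless
    data.to_csv(path, index=False)
    meta = {"n": int(len(data)), "columns": list(data.columns)}
    if seed is not None:
        meta["seed"] = int(seed)
    elif config is not None:
        meta["seed"] = int(config.seed)
    if config is not None:
        meta["config"] = _config_dict(config)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort`."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"cohort file missing columns: {missing}")
    df = df[list(COHORT_COLUMNS)]
    for col in COHORT_COLUMNS:
        if col == "cohort":
            continue
        dtype = int if col in ("steam_pop", "transmural") else float
        df[col] = df[col].astype(dtype)
    return df
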