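"""Parameter containers, units, and configuration loading.

The model lives in a 1D compartmentalized tissue: producing cell rows
``x_p ∈ {0..N_P-1}`` and receiving rows ``x_r ∈ {0..N_R-1}`` are both counted
outward from the compartment border, so the separation between row ``x_p`` and
row ``x_r`` is ``x_p + x_r`` cell diameters.  Lengths are measured in μm
externally and converted to cell diameters (dividing by the mean cell diameter
``phi``) internally; time is in seconds.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ConfigurationError",
    "TissueConfig",
    "LengthStats",
    "CytonemeParams",
    "ContactParams",
    "SimulationParams",
    "Config",
    "to_cell_diameters",
    "from_cell_diameters",
    "load_parameter_table",
    "write_parameter_table",
    "validate_config",
    "load_config",
    "set_by_path",
    "wing_disc_config",
    "histoblast_config",
]


class ConfigurationError(ValueError):
    """Raised when a parameter table or config violates an invariant."""


# ---------------------------------------------------------------------------
# unit helpers
# ---------------------------------------------------------------------------

def to_cell_diameters(value_um: float, phi: float) -> float:
    """Convert a length in μm to cell diameters (divide by cell size ``phi``)."""
    if phi <= 0:
        raise ConfigurationError(f"cell diameter phi must be positive, got {phi}")
    return value_um / phi


def from_cell_diameters(value_cd: float, phi: float) -> float:
    """Inverse of :func:`to_cell_diameters`."""
    if phi <= 0:
        raise ConfigurationError(f"cell diameter phi must be positive, got {phi}")
    return value_cd * phi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TissueConfig:
    """1D tissue geometry: cell diameter and producing/receiving row counts."""

    phi: float = 3.05              # mean cell diameter, μm
    n_producing_rows: int = 15     # N_P
    n_receiving_rows: int = 10     # N_R

    def __post_init__(self) -> None:
        if self.phi <= 0:
            raise ConfigurationError(f"phi must be > 0, got {self.phi}")
        if self.n_producing_rows < 1:
            raise ConfigurationError(
                f"n_producing_rows must be >= 1, got {self.n_producing_rows}")
        if self.n_receiving_rows < 1:
            raise ConfigurationError(
                f"n_receiving_rows must be >= 1, got {self.n_receiving_rows}")

    def separation(self, x_p: int, x_r: int) -> int:
        """Distance between producing row x_p and receiving row x_r, in cells."""
        return x_p + x_r


@dataclass(frozen=True)
class LengthStats:
    """Summary (and optionally raw sample) of a cytoneme length distribution.

    ``lambda_max`` is operationalized as mean + 1 SD, the convention under
    which the printed range arithmetic (11.8+4.1 → 15.9 μm; 14.5+5.5 → 20 μm)
    is consistent.
    """

    mean_um: float
    sd_um: float = 0.0
    samples_um: tuple[float, ...] | None = None
    compartment: str = "receiving"

    def __post_init__(self) -> None:
        if self.mean_um <= 0:
            raise ConfigurationError(f"mean length must be > 0, got {self.mean_um}")
        if self.sd_um < 0:
            raise ConfigurationError(f"length SD must be >= 0, got {self.sd_um}")
        if self.compartment not in ("producing", "receiving"):
            raise ConfigurationError(f"unknown compartment {self.compartment!r}")
        if self.samples_um is not None:
            s = np.asarray(self.samples_um, dtype=float)
            if s.size and (s <= 0).all():
                raise ConfigurationError("length samples are all non-positive")
            if s.size and (s < 0).any():
                raise ConfigurationError("negative cytoneme lengths in sample")

    @property
    def lambda_max_um(self) -> float:
        return self.mean_um + self.sd_um

    @classmethod
    def from_samples(cls, samples_um: Sequence[float], compartment: str = "receiving",
                     ddof: int = 1) -> "LengthStats":
        """Build stats from a raw sample vector (unbiased SD by default)."""
        s = np.asarray(samples_um, dtype=float)
        if s.size == 0:
            raise ConfigurationError("empty length sample")
        if (s < 0).any():
            raise ConfigurationError("negative cytoneme lengths in sample")
        sd = float(np.std(s, ddof=ddof)) if s.size > ddof else 0.0
        return cls(mean_um=float(np.mean(s)), sd_um=sd,
                   samples_um=tuple(float(v) for v in s), compartment=compartment)


@dataclass(frozen=True)
class CytonemeParams:
    """Cytoneme life-cycle parameters shared by one simulation.

    Elongation/retraction velocities are in μm/s; note the literature values
    behind the defaults are placeholders (see the methods note), as typical
    filopodial velocities rather than measured ones.
    """

    length_stats_r: LengthStats = field(
        default_factory=lambda: LengthStats(11.8, 4.1, compartment="receiving"))
    length_stats_p: LengthStats = field(
        default_factory=lambda: LengthStats(14.5, 5.5, compartment="producing"))
    v_elong_um_s: float = 0.1
    v_retract_um_s: float = 0.1
    t_stationary_mean_s: float = 60.0
    t_stationary_samples_s: tuple[float, ...] | None = None
    fraction_triangular: float = 0.5
    n_cyt: int = 4
    creation_gap_s: float = 0.0
    contact_while_growing_triangular: bool = True
    contact_while_growing_trapezoidal: bool = True
    static: bool = False

    def __post_init__(self) -> None:
        if self.v_elong_um_s <= 0 or self.v_retract_um_s <= 0:
            raise ConfigurationError("cytoneme velocities must be > 0")
        if not 0.0 <= self.fraction_triangular <= 1.0:
            raise ConfigurationError(
                f"fraction_triangular must be in [0,1], got {self.fraction_triangular}")
        if self.n_cyt < 0:
            raise ConfigurationError(f"n_cyt must be >= 0, got {self.n_cyt}")
        if self.t_stationary_mean_s < 0:
            raise ConfigurationError("stationary-time mean must be >= 0")
        if self.creation_gap_s < 0:
            raise ConfigurationError("creation gap must be >= 0")


@dataclass(frozen=True)
class ContactParams:
    """Contact mechanism: type 1/2/3, probability model ψ, and contact time tc."""

    contact_type: int = 3
    psi_variant: str = "constant"     # constant | position | multiple
    mu: float = 1.0
    tc_s: float = 60.0
    allow_cyt_cyt: bool = True        # type 3 only
    psi_range_max: float | None = None  # rows; defaults to N_R for psi(mu, x)

    def __post_init__(self) -> None:
        if self.contact_type not in (1, 2, 3):
            raise ConfigurationError(f"contact_type must be 1, 2 or 3, got {self.contact_type}")
        if self.psi_variant not in ("constant", "position", "multiple"):
            raise ConfigurationError(f"unknown psi_variant {self.psi_variant!r}")
        if not 0.0 <= self.mu <= 1.0:
            raise ConfigurationError(f"mu must be in [0,1], got {self.mu}")
        if self.tc_s < 0:
            raise ConfigurationError(f"tc must be >= 0, got {self.tc_s}")


@dataclass(frozen=True)
class SimulationParams:
    """Replicate count, horizon, time step, morphogen kinetics and seed."""

    total_time_s: float = 3600.0
    dt_s: float = 1.0
    n_replicates: int = 200
    seed: int = 0
    alpha: float = 1.0                     # morphogen units per contact
    half_life_s: float = 166.0 * 60.0      # Hh degradation half-life
    record_every: int | None = None        # time-series recording stride (bins)

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ConfigurationError(f"dt must be > 0, got {self.dt_s}")
        if self.total_time_s < self.dt_s:
            raise ConfigurationError("total time must be >= dt")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be > 0")
        if not (self.half_life_s > 0):
            raise ConfigurationError("half-life must be > 0 (use math.inf for no decay)")

    @property
    def delta(self) -> float:
        """Degradation rate δ = ln2 / half-life (0 for infinite half-life)."""
        return 0.0 if math.isinf(self.half_life_s) else math.log(2.0) / self.half_life_s

    @property
    def n_bins(self) -> int:
        return max(1, int(round(self.total_time_s / self.dt_s)))


@dataclass(frozen=True)
class Config:
    """Full, validated simulation configuration."""

    tissue: TissueConfig = field(default_factory=TissueConfig)
    cytonemes: CytonemeParams = field(default_factory=CytonemeParams)
    contact: ContactParams = field(default_factory=ContactParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------

_LENGTH_COLS = ("length_um",)
_STAT_COLS = ("mean_um", "sd_um")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def load_parameter_table(path: str | Path):
    """Read a cytoneme parameter table (CSV/TSV, optionally xlsx).

    Expected columns: ``compartment`` (producing|receiving) plus either a long
    format ``length_um`` column (one measured cytoneme per row) or summary
    columns ``mean_um``/``sd_um``.  Optional columns: ``v_elong_um_s``,
    ``v_retract_um_s``, ``t_stationary_s``, ``behavior``
    (triangular|trapezoidal).

    Returns ``(CytonemeParams, (LengthStats_receiving, LengthStats_producing))``.
    Raw samples are retained when present; summary stats are used directly when
    no samples are given.
    """
    df = _read_table(path)
    if "compartment" not in df.columns:
        raise ConfigurationError("parameter table is missing required column 'compartment'")
    has_samples = "length_um" in df.columns and df["length_um"].notna().any()
    has_stats = all(c in df.columns for c in _STAT_COLS)
    if not has_samples and not has_stats:
        raise ConfigurationError(
            "parameter table needs either a 'length_um' sample column or "
            "'mean_um'/'sd_um' summary columns")

    stats: dict[str, LengthStats] = {}
    for comp in ("receiving", "producing"):
        sub = df[df["compartment"] == comp]
        if sub.empty:
            raise ConfigurationError(f"no rows for compartment {comp!r}")
        if has_samples and sub["length_um"].notna().any():
            samples = sub["length_um"].dropna().to_numpy(dtype=float)
            if (samples < 0).any():
                raise ConfigurationError(f"negative cytoneme lengths for {comp!r}")
            stats[comp] = LengthStats.from_samples(samples, compartment=comp)
        else:
            row = sub.dropna(subset=["mean_um"]).iloc[0]
            stats[comp] = LengthStats(float(row["mean_um"]), float(row.get("sd_um", 0.0)),
                                      compartment=comp)

    def _first(col: str, default: float) -> float:
        if col in df.columns and df[col].notna().any():
            return float(df[col].dropna().iloc[0])
        return default

    kwargs: dict[str, Any] = dict(
        length_stats_r=stats["receiving"],
        length_stats_p=stats["producing"],
        v_elong_um_s=_first("v_elong_um_s", 0.1),
        v_retract_um_s=_first("v_retract_um_s", 0.1),
    )
    if "t_stationary_s" in df.columns and df["t_stationary_s"].notna().any():
        ts = tuple(float(v) for v in df["t_stationary_s"].dropna())
        kwargs["t_stationary_samples_s"] = ts
        kwargs["t_stationary_mean_s"] = float(np.mean(ts))
    if "behavior" in df.columns and df["behavior"].notna().any():
        beh = df["behavior"].dropna().str.lower()
        kwargs["fraction_triangular"] = float((beh == "triangular").mean())
    params = CytonemeParams(**kwargs)
    return params, (stats["receiving"], stats["producing"])


def write_parameter_table(params: CytonemeParams, path: str | Path) -> None:
    """Write a parameter table that :func:`load_parameter_table` round-trips."""
    rows = []
    for stats in (params.length_stats_r, params.length_stats_p):
        if stats.samples_um is not None:
            for v in stats.samples_um:
                rows.append({"compartment": stats.compartment, "length_um": v})
        else:
            rows.append({"compartment": stats.compartment,
                         "mean_um": stats.mean_um, "sd_um": stats.sd_um})
    df = pd.DataFrame(rows)
    df["v_elong_um_s"] = np.nan
    df["v_retract_um_s"] = np.nan
    df.loc[df.index[0], "v_elong_um_s"] = params.v_elong_um_s
    df.loc[df.index[0], "v_retract_um_s"] = params.v_retract_um_s
    if params.t_stationary_samples_s is not None:
        ts = list(params.t_stationary_samples_s)
        df["t_stationary_s"] = pd.Series(ts + [np.nan] * (len(df) - len(ts)))
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# config assembly
# ---------------------------------------------------------------------------

def _build_section(cls, mapping: Mapping[str, Any]):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} for section {cls.__name__}")
    return cls(**mapping)


def _length_stats_from(obj: Any, compartment: str) -> LengthStats:
    if isinstance(obj, LengthStats):
        return obj
    if isinstance(obj, Mapping):
        d = dict(obj)
        d.setdefault("compartment", compartment)
        if "samples_um" in d and d["samples_um"] is not None:
            d["samples_um"] = tuple(float(v) for v in d["samples_um"])
        return LengthStats(**d)
    raise ConfigurationError(f"cannot build LengthStats from {obj!r}")


def validate_config(config: Config | Mapping[str, Any]) -> Config:
    """Validate a config mapping, fill reference defaults, normalize it.

    Defaults correspond to the reference wing-disc case (N_P=15, n_cyt=4,
    ϕ=3.05 μm, contact type 3, μ=1, tc=60 s).  A type-3 config with cyt-cyt
    contacts disabled is legal but warned about, since it degrades type 3 to
    body contacts only.
    """
    if isinstance(config, Config):
        cfg = config
    else:
        d = {k: dict(v) if isinstance(v, Mapping) else v for k, v in dict(config).items()}
        unknown = set(d) - {"tissue", "cytonemes", "contact", "simulation"}
        if unknown:
            raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")
        cyt = d.get("cytonemes", {})
        if "length_stats_r" in cyt:
            cyt["length_stats_r"] = _length_stats_from(cyt["length_stats_r"], "receiving")
        if "length_stats_p" in cyt:
            cyt["length_stats_p"] = _length_stats_from(cyt["length_stats_p"], "producing")
        if "t_stationary_samples_s" in cyt and cyt["t_stationary_samples_s"] is not None:
            cyt["t_stationary_samples_s"] = tuple(float(v) for v in cyt["t_stationary_samples_s"])
        cfg = Config(
            tissue=_build_section(TissueConfig, d.get("tissue", {})),
            cytonemes=_build_section(CytonemeParams, cyt),
            contact=_build_section(ContactParams, d.get("contact", {})),
            simulation=_build_section(SimulationParams, d.get("simulation", {})),
        )
    if cfg.contact.contact_type == 3 and not cfg.contact.allow_cyt_cyt:
        warnings.warn(
            "contact type 3 with cyt-cyt contacts disabled behaves as body "
            "contacts only (reach limited to min(λ_r, λ_p))", UserWarning,
            stacklevel=2)
    return cfg


def load_config(path: str | Path) -> Config:
    """Load and validate a YAML or JSON config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return validate_config(data or {})


def set_by_path(config: Config, path: str, value: Any) -> Config:
    """Return a copy of ``config`` with the dotted-path scalar field replaced.

    Example: ``set_by_path(cfg, "contact.mu", 0.4)``.
    """
    section, _, fname = path.partition(".")
    if not fname:
        raise ConfigurationError(f"parameter path must be 'section.field', got {path!r}")
    if not hasattr(config, section):
        raise ConfigurationError(f"unknown config section {section!r}")
    sub = getattr(config, section)
    if not any(f.name == fname for f in dataclasses.fields(sub)):
        raise ConfigurationError(f"unknown field {fname!r} in section {section!r}")
    new_sub = dataclasses.replace(sub, **{fname: value})
    return dataclasses.replace(config, **{section: new_sub})


# ---------------------------------------------------------------------------
# tissue presets
# ---------------------------------------------------------------------------

def wing_disc_config(**overrides: Any) -> Config:
    """Reference wing imaginal disc configuration (measured ϕ and lengths)."""
    cfg = Config()
    for path, value in overrides.items():
        cfg = set_by_path(cfg, path, value)
    return validate_config(cfg)


def histoblast_config(**overrides: Any) -> Config:
    """Abdominal histoblast nest configuration.

    ϕ and the Hh half-life are measured values; the histoblast cytoneme length
    statistics are shorter-than-wing-disc placeholders (the source
    measurements are not printed), documented in the methods note.
    """
    cfg = Config(
        tissue=TissueConfig(phi=4.37, n_producing_rows=15, n_receiving_rows=8),
        cytonemes=CytonemeParams(
            length_stats_r=LengthStats(7.3, 2.5, compartment="receiving"),
            length_stats_p=LengthStats(8.9, 3.2, compartment="producing"),
        ),
    )
    for path, value in overrides.items():
        cfg = set_by_path(cfg, path, value)
    return validate_config(cfg)
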