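"""Cytoneme length trajectories λ(t).

A cytoneme life cycle is piecewise linear: elongation at velocity ``v_e`` up
to ``λ_max``, an optional stationary plateau (trapezoidal behavior; the
plateau is absent for triangular behavior), then retraction at ``v_r``.
Static cytonemes hold ``λ_max`` for the whole simulated time.  Trajectories
are evaluated analytically at arbitrary ``t``, so the simulation time step
only affects contact bookkeeping, never lengths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import ConfigurationError, CytonemeParams, LengthStats

__all__ = [
    "CytonemeTrajectory",
    "sample_length",
    "sample_stationary_time",
    "build_trajectory",
    "length_at",
    "generate_cycle_schedule",
    "synthetic_length_samples",
]

TRIANGULAR = "triangular"
TRAPEZOIDAL = "trapezoidal"
STATIC = "static"


@dataclass(frozen=True)
class CytonemeTrajectory:
    """One cytoneme life cycle; lengths in cell diameters, times in seconds."""

    behavior: str
    lambda_max: float           # cell diameters
    t_start: float
    t_elong: float
    t_stationary: float
    t_retract: float
    compartment: str = "receiving"
    row: int = 0

    def __post_init__(self) -> None:
        if self.behavior not in (TRIANGULAR, TRAPEZOIDAL, STATIC):
            raise ConfigurationError(f"unknown behavior {self.behavior!r}")
        if self.lambda_max < 0:
            raise ConfigurationError("lambda_max must be >= 0")
        if self.t_stationary < 0:
            raise ConfigurationError("stationary time must be >= 0")
        if self.behavior == TRIANGULAR and self.t_stationary != 0:
            raise ConfigurationError("triangular cycles have no stationary plateau")

    @property
    def lifetime(self) -> float:
        if self.behavior == STATIC:
            return np.inf
        return self.t_elong + self.t_stationary + self.t_retract

    @property
    def t_peak_start(self) -> float:
        return self.t_start + self.t_elong

    @property
    def t_peak_end(self) -> float:
        return self.t_start + self.t_elong + self.t_stationary


def sample_length(stats: LengthStats, phi: float, rng: np.random.Generator) -> float:
    """Draw one maximum length, in cell diameters.

    With raw samples present the draw is uniform over the empirical sample;
    otherwise a truncated normal on (0, ∞) with the stated mean and SD.
    """
    if stats.samples_um is not None:
        s = np.asarray(stats.samples_um, dtype=float)
        s = s[s > 0]
        if s.size == 0:
            raise ConfigurationError("length sample has no positive values")
        return float(rng.choice(s)) / phi
    if stats.sd_um == 0.0:
        return stats.mean_um / phi
    a = (0.0 - stats.mean_um) / stats.sd_um
    draw = sps.truncnorm.rvs(a, np.inf, loc=stats.mean_um, scale=stats.sd_um,
                             random_state=rng)
    return float(draw) / phi


def sample_stationary_time(params: CytonemeParams, rng: np.random.Generator) -> float:
    """Draw a plateau duration: empirical table when given, else exponential."""
    if params.t_stationary_samples_s is not None:
        return float(rng.choice(np.asarray(params.t_stationary_samples_s, dtype=float)))
    if params.t_stationary_mean_s == 0.0:
        return 0.0
    return float(rng.exponential(params.t_stationary_mean_s))


def build_trajectory(lambda_max: float, behavior: str, v_e: float, v_r: float,
                     t_stationary: float, t_start: float, phi: float,
                     compartment: str = "receiving", row: int = 0) -> CytonemeTrajectory:
    """Assemble a piecewise-linear trajectory.

    ``lambda_max`` is in cell diameters; phase durations follow from the
    velocities in μm/s via ``t_elong = λ_max·ϕ/v_e`` (and likewise for
    retraction).
    """
    if lambda_max < 0:
        raise ConfigurationError("lambda_max must be >= 0")
    if v_e <= 0 or v_r <= 0:
        raise ConfigurationError("velocities must be > 0")
    if t_stationary < 0:
        raise ConfigurationError("stationary time must be >= 0")
    if behavior == STATIC:
        return CytonemeTrajectory(STATIC, lambda_max, t_start, 0.0, 0.0, 0.0,
                                  compartment, row)
    ts = 0.0 if behavior == TRIANGULAR else t_stationary
    return CytonemeTrajectory(
        behavior, lambda_max, t_start,
        t_elong=lambda_max * phi / v_e,
        t_stationary=ts,
        t_retract=lambda_max * phi / v_r,
        compartment=compartment, row=row)


def length_at(traj: CytonemeTrajectory, t):
    """Evaluate λ(t) exactly (vectorized over ``t``), in cell diameters."""
    scalar = np.isscalar(t) or np.ndim(t) == 0
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if traj.behavior == STATIC:
        out = np.full_like(t, traj.lambda_max)
        return float(out[0]) if scalar else out
    xp = [traj.t_start, traj.t_peak_start, traj.t_peak_end,
          traj.t_start + traj.lifetime]
    fp = [0.0, traj.lambda_max, traj.lambda_max, 0.0]
    out = np.interp(t, xp, fp, left=0.0, right=0.0)
    out[t < traj.t_start] = 0.0
    out[t > traj.t_start + traj.lifetime] = 0.0
    return float(out[0]) if scalar else out


def generate_cycle_schedule(params: CytonemeParams, total_time: float,
                            rng: np.random.Generator, *, compartment: str,
                            n_rows: int, phi: float) -> list[list[list[CytonemeTrajectory]]]:
    """Tile consecutive life cycles over ``[0, total_time]``.

    Returns ``schedule[row][slot] -> list of trajectories`` for each of the
    ``n_cyt`` cytoneme slots of each cell row.  Each cycle re-samples its
    maximum length and draws its behavior Bernoulli(fraction_triangular);
    consecutive cycles in a slot are separated by the creation gap.
    """
    if total_time <= 0:
        raise ConfigurationError("total_time must be > 0")
    stats = params.length_stats_r if compartment == "receiving" else params.length_stats_p
    schedule: list[list[list[CytonemeTrajectory]]] = []
    for row in range(n_rows):
        slots: list[list[CytonemeTrajectory]] = []
        for _ in range(params.n_cyt):
            cycles: list[CytonemeTrajectory] = []
            if params.static:
                lam = sample_length(stats, phi, rng)
                cycles.append(build_trajectory(lam, STATIC, params.v_elong_um_s,
                                               params.v_retract_um_s, 0.0, 0.0,
                                               phi, compartment, row))
            else:
                t = 0.0
                while t < total_time:
                    lam = sample_length(stats, phi, rng)
                    behavior = (TRIANGULAR if rng.random() < params.fraction_triangular
                                else TRAPEZOIDAL)
                    t_stat = (sample_stationary_time(params, rng)
                              if behavior == TRAPEZOIDAL else 0.0)
                    traj = build_trajectory(lam, behavior, params.v_elong_um_s,
                                            params.v_retract_um_s, t_stat, t,
                                            phi, compartment, row)
                    cycles.append(traj)
                    step = traj.lifetime + params.creation_gap_s
                    if step <= 0:
                        break
                    t += step
            slots.append(cycles)
        schedule.append(slots)
    return schedule


def synthetic_length_samples(mean_um: float, sd_um: float, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Generate a synthetic measured-length sample (truncated normal on (0,∞)).

    Stand-in for a table of manually measured cytoneme lengths; the bounded
    empirical support mirrors what loading real measurements provides.
    """
    a = (0.0 - mean_um) / sd_um
    return sps.truncnorm.rvs(a, np.inf, loc=mean_um, scale=sd_um, size=n,
                             random_state=rng)
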