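"""Ensemble orchestration: replicates, morphogen accumulation, FRAP runs.

Each replicate draws independent cytoneme schedules, realizes contacts, and
accumulates morphogen per receiving row as

    u(x, t+dt) = u(x, t) · exp(−δ·dt) + α · ΔN(x, t→t+dt),   u(x, 0) = 0,

i.e. every contact transfers a fixed amount α and the accumulated signal
decays exponentially with the degradation rate δ = ln2/half-life.  Ensemble
mean and SD are taken across replicates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .config import Config, ConfigurationError, set_by_path, validate_config
from .contacts import ContactField, count_contacts
from .dynamics import generate_cycle_schedule

__all__ = [
    "GradientResult",
    "FrapResult",
    "run_replicate",
    "run_ensemble",
    "run_frap",
    "detect_steady_state",
    "scan_parameter",
    "gradient_extent",
]

STEADY_STATE_NOT_REACHED = -1


@dataclass
class GradientResult:
    """Ensemble output of a simulation.

    ``u_final`` holds the per-replicate morphogen field at the end of the run
    (replicates × receiving rows); ``contacts_total`` the per-replicate
    cumulative contact counts; ``mean_u_t`` the ensemble-mean field at the
    recorded times.
    """

    config: Config
    seed: int
    t_recorded: np.ndarray          # (n_rec,) seconds
    mean_u_t: np.ndarray            # (n_rows, n_rec)
    u_final: np.ndarray             # (n_rep, n_rows)
    contacts_total: np.ndarray      # (n_rep, n_rows) int
    single_replicate: bool = field(default=False)

    @property
    def n_replicates(self) -> int:
        return self.u_final.shape[0]

    @property
    def mean(self) -> np.ndarray:
        """Ensemble mean of the final morphogen field per row."""
        return self.u_final.mean(axis=0)

    @property
    def sd(self) -> np.ndarray:
        """Ensemble SD per row (0, flagged, for a single replicate)."""
        if self.single_replicate:
            return np.zeros(self.u_final.shape[1])
        return self.u_final.std(axis=0, ddof=1)

    @property
    def mean_contacts(self) -> np.ndarray:
        return self.contacts_total.mean(axis=0)

    def contacts_at(self, x_r: int = 0) -> np.ndarray:
        """Per-replicate cumulative contacts at receiving row ``x_r``."""
        return self.contacts_total[:, x_r]


def _replicate_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive per-replicate generators from one master seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _build_schedules(config: Config, rng: np.random.Generator):
    tissue, cyt, sim = config.tissue, config.cytonemes, config.simulation
    ctype = config.contact.contact_type
    recv = prod = None
    if ctype in (1, 3):
        recv = generate_cycle_schedule(cyt, sim.total_time_s, rng,
                                       compartment="receiving",
                                       n_rows=tissue.n_receiving_rows,
                                       phi=tissue.phi)
    if ctype in (2, 3):
        prod = generate_cycle_schedule(cyt, sim.total_time_s, rng,
                                       compartment="producing",
                                       n_rows=tissue.n_producing_rows,
                                       phi=tissue.phi)
    return recv, prod


def _integrate(counts: np.ndarray, alpha: float, delta: float, dt: float) -> np.ndarray:
    """Accumulate-and-decay filter over time bins (axis 1)."""
    decay = math.exp(-delta * dt)
    return lfilter([alpha], [1.0, -decay], counts.astype(float), axis=1)


def run_replicate(config: Config, replicate_seed) -> tuple[ContactField, np.ndarray]:
    """Run one replicate; returns the contact field and u(x_r, t)."""
    config = validate_config(config)
    rng = (replicate_seed if isinstance(replicate_seed, np.random.Generator)
           else np.random.default_rng(replicate_seed))
    recv, prod = _build_schedules(config, rng)
    fieldc = count_contacts(recv, prod, config, rng)
    sim = config.simulation
    u = _integrate(fieldc.counts, sim.alpha, sim.delta, sim.dt_s)
    return fieldc, u


def _record_stride(config: Config) -> int:
    sim = config.simulation
    if sim.record_every is not None:
        return max(1, sim.record_every)
    return max(1, sim.n_bins // 500)


def run_ensemble(config: Config) -> GradientResult:
    """Run ``n_replicates`` independent replicates with derived seeds."""
    config = validate_config(config)
    sim, tissue = config.simulation, config.tissue
    nt = sim.n_bins
    stride = _record_stride(config)
    rec_idx = np.arange(stride - 1, nt, stride)
    t_recorded = (rec_idx + 1) * sim.dt_s
    n_rows = tissue.n_receiving_rows

    rngs = _replicate_rngs(sim.seed, sim.n_replicates)
    u_final = np.zeros((sim.n_replicates, n_rows))
    contacts_total = np.zeros((sim.n_replicates, n_rows), dtype=np.int64)
    sum_u_t = np.zeros((n_rows, rec_idx.size))
    for i, rng in enumerate(rngs):
        fieldc, u = run_replicate(config, rng)
        u_final[i] = u[:, -1]
        contacts_total[i] = fieldc.total_per_row
        sum_u_t += u[:, rec_idx]
    single = sim.n_replicates == 1
    if single:
        warnings.warn("single-replicate ensemble: SD reported as 0", UserWarning,
                      stacklevel=2)
    return GradientResult(config=config, seed=sim.seed, t_recorded=t_recorded,
                          mean_u_t=sum_u_t / sim.n_replicates, u_final=u_final,
                          contacts_total=contacts_total, single_replicate=single)


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapResult:
    """Photobleaching recovery: fraction of the pre-bleach field over time."""

    config: Config
    bleach_time_s: float
    bleach_fraction: float
    times_s: np.ndarray             # sampled post-bleach times (s)
    recovery_mean: np.ndarray       # mean over replicates
    recovery_sd: np.ndarray
    prebleach_mean: np.ndarray      # ensemble-mean field at bleach time

    def recovery_at(self, t_s: float) -> float:
        """Interpolated mean recovery fraction at ``t_s`` after bleaching."""
        return float(np.interp(t_s, self.times_s, self.recovery_mean))


def run_frap(config: Config, bleach_time_s: float, bleach_fraction: float,
             sample_interval_s: float = 45.0) -> FrapResult:
    """Simulate photobleaching: scale u by (1−bleach_fraction) at bleach time.

    Bleaching removes fluorophore from the accumulated signal only; cytoneme
    transport continues unchanged.  By linearity the bleached trajectory is
    the unbleached one minus the bleached amount decaying at rate δ, which is
    used here instead of re-integrating.  Recovery is reported relative to the
    fixed pre-bleach profile, averaged over rows carrying signal (ensemble
    pre-bleach mean ≥ 1% of its max), sampled every ``sample_interval_s``.
    """
    config = validate_config(config)
    if not 0.0 <= bleach_fraction <= 1.0:
        raise ConfigurationError("bleach_fraction must be in [0, 1]")
    sim, tissue = config.simulation, config.tissue
    dt = sim.dt_s
    nt = sim.n_bins
    bleach_bin = int(round(bleach_time_s / dt))
    if not 0 < bleach_bin < nt:
        raise ConfigurationError("bleach time must fall inside the simulated window")
    delta = sim.delta
    post_idx = bleach_bin - 1 + np.arange(0, nt - bleach_bin + 1,
                                          max(1, int(round(sample_interval_s / dt))))
    post_idx = post_idx[post_idx < nt]
    times_s = (post_idx - (bleach_bin - 1)) * dt

    rngs = _replicate_rngs(sim.seed, sim.n_replicates)
    n_rows = tissue.n_receiving_rows
    u_pre_sum = np.zeros(n_rows)
    u_pre_all = np.zeros((sim.n_replicates, n_rows))
    u_post_all = np.zeros((sim.n_replicates, n_rows, post_idx.size))
    for i, rng in enumerate(rngs):
        _, u = run_replicate(config, rng)
        u_pre = u[:, bleach_bin - 1]
        decay_back = np.exp(-delta * (post_idx - (bleach_bin - 1)) * dt)
        u_b = u[:, post_idx] - bleach_fraction * u_pre[:, None] * decay_back[None, :]
        u_pre_all[i] = u_pre
        u_post_all[i] = u_b
        u_pre_sum += u_pre
    u_pre_mean = u_pre_sum / sim.n_replicates
    if not np.any(u_pre_mean > 0):
        warnings.warn("bleach applied before any signal accumulated", UserWarning,
                      stacklevel=2)
        rows = np.zeros(n_rows, dtype=bool)
        rows[0] = True
    else:
        rows = u_pre_mean >= 0.01 * u_pre_mean.max()
    denom = np.where(u_pre_mean[rows] > 0, u_pre_mean[rows], np.nan)
    ratios = u_post_all[:, rows, :] / denom[None, :, None]
    rec_per_rep = np.nanmean(ratios, axis=1)        # (n_rep, n_times)
    recovery_mean = rec_per_rep.mean(axis=0)
    recovery_sd = (rec_per_rep.std(axis=0, ddof=1) if sim.n_replicates > 1
                   else np.zeros_like(recovery_mean))
    return FrapResult(config=config, bleach_time_s=bleach_time_s,
                      bleach_fraction=bleach_fraction, times_s=times_s,
                      recovery_mean=recovery_mean, recovery_sd=recovery_sd,
                      prebleach_mean=u_pre_mean)


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------

def detect_steady_state(result: GradientResult, rel_tol: float = 0.01,
                        window_s: float | None = None) -> int:
    """First recorded time index after which the ensemble-mean gradient is flat.

    Flatness: the L∞ relative change between consecutive recorded samples
    stays below ``rel_tol`` over a trailing window (default 5 degradation
    half-lives).  Returns ``STEADY_STATE_NOT_REACHED`` with a warning when no
    such index exists.
    """
    if not math.isfinite(rel_tol):
        return 0
    u = result.mean_u_t
    t = result.t_recorded
    if u.shape[1] < 2:
        warnings.warn("too few recorded samples for steady-state detection",
                      UserWarning, stacklevel=2)
        return STEADY_STATE_NOT_REACHED
    if window_s is None:
        window_s = 5.0 * result.config.simulation.half_life_s
        if not math.isfinite(window_s):
            window_s = t[-1] - t[0]
    scale = np.abs(u).max()
    if scale == 0:
        return 0
    rel = np.abs(np.diff(u, axis=1)).max(axis=0) / scale   # (n_rec-1,)
    flat = rel < rel_tol
    interval = t[1] - t[0]
    w_bins = min(rel.size, max(1, int(math.ceil(window_s / interval))))
    for i in range(rel.size - w_bins + 1):
        if flat[i:i + w_bins].all():
            return i
    warnings.warn("steady state not reached within the simulated window",
                  UserWarning, stacklevel=2)
    return STEADY_STATE_NOT_REACHED


def scan_parameter(config: Config, parameter_path: str, values) -> list[GradientResult]:
    """One ensemble per value of a scalar config field (shared derived seeds)."""
    config = validate_config(config)
    return [run_ensemble(set_by_path(config, parameter_path, v)) for v in values]


def gradient_extent(result: GradientResult, threshold: float = 0.0) -> int:
    """Number of receiving rows carrying signal.

    Counts rows whose ensemble-mean cumulative contacts exceed ``threshold``
    times the maximum row mean (``threshold=0``: any nonzero mean).  Returns
    the index of the last such row plus one (a length in cell rows).
    """
    mean_n = result.mean_contacts
    if mean_n.max() <= 0:
        return 0
    above = mean_n > threshold * mean_n.max()
    return int(np.nonzero(above)[0][-1]) + 1
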