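"""Shared fixtures and the independent brute-force contact oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest

import cytograd as cg


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def small_config(**overrides):
    """A fast dynamic reference-style configuration for ensemble tests."""
    base = {
        "tissue": {"phi": 3.05, "n_producing_rows": 6, "n_receiving_rows": 6},
        "cytonemes": {
            "length_stats_r": {"mean_um": 11.8, "sd_um": 4.1},
            "length_stats_p": {"mean_um": 14.5, "sd_um": 5.5},
            "n_cyt": 2,
        },
        "contact": {"contact_type": 3, "mu": 1.0, "tc_s": 10.0},
        "simulation": {"total_time_s": 600.0, "dt_s": 1.0, "n_replicates": 50,
                       "seed": 11, "half_life_s": math.inf},
    }
    for section, kv in overrides.items():
        base.setdefault(section, {}).update(kv)
    return cg.validate_config(base)


@pytest.fixture
def small_config_factory():
    return small_config


# ---------------------------------------------------------------------------
# brute-force oracle: pure-python re-derivation of the contact rules
# ---------------------------------------------------------------------------

def _oracle_length(traj, t: float) -> float:
    if traj.behavior == "static":
        return traj.lambda_max
    rel = t - traj.t_start
    if rel < 0:
        return 0.0
    if rel <= traj.t_elong:
        if traj.t_elong == 0:
            return traj.lambda_max
        return traj.lambda_max * rel / traj.t_elong
    rel -= traj.t_elong
    if rel <= traj.t_stationary:
        return traj.lambda_max
    rel -= traj.t_stationary
    if rel <= traj.t_retract and traj.t_retract > 0:
        return traj.lambda_max * (1.0 - rel / traj.t_retract)
    return 0.0


def _oracle_state(cycles, t: float, bin_index: int, dt: float,
                  cwg_tri: bool, cwg_trap: bool):
    """Contact-relevant length and active flag of one cytoneme slot at time t.

    Under contact-after-growth the cytoneme contacts at maximum elongation:
    in the bin containing the triangular peak (or overlapping the trapezoidal
    plateau) the relevant length is λ_max.
    """
    lam, active = 0.0, False
    for traj in cycles:
        if traj.behavior == "static":
            lam = max(lam, traj.lambda_max)
            active = True
            continue
        lam_c = _oracle_length(traj, t)
        lam = max(lam, lam_c)
        cwg = cwg_tri if traj.behavior == "triangular" else cwg_trap
        if cwg:
            active = active or lam_c > 0
        elif traj.behavior == "triangular":
            if int(traj.t_peak_start // dt) == bin_index:
                active = True
                lam = max(lam, traj.lambda_max)
        else:
            if (int(traj.t_peak_start // dt) <= bin_index
                    <= int(traj.t_peak_end // dt)):
                active = True
                lam = max(lam, traj.lambda_max)
    return lam, active


def brute_force_contacts(recv_sched, prod_sched, config) -> np.ndarray:
    """Independent enumeration of contacts for μ=1, tc=0, ψ(μ) constant.

    Walks every pair and time bin, emitting one contact at the first bin of
    each eligibility episode, exactly the refractory rule stated for the
    engine.
    """
    tissue, contact, sim, cyt = (config.tissue, config.contact,
                                 config.simulation, config.cytonemes)
    assert contact.mu == 1.0 and contact.tc_s == 0.0
    nt, dt = sim.n_bins, sim.dt_s
    n_r, n_p = tissue.n_receiving_rows, tissue.n_producing_rows
    cwg = (cyt.contact_while_growing_triangular,
           cyt.contact_while_growing_trapezoidal)
    counts = np.zeros((n_r, nt), dtype=int)

    def pair_iter(x_r, x_p):
        if contact.contact_type == 1:
            for cycles in recv_sched[x_r]:
                yield (cycles, None)
        elif contact.contact_type == 2:
            for cycles in prod_sched[x_p]:
                yield (None, cycles)
        else:
            for cr in recv_sched[x_r]:
                for cp in prod_sched[x_p]:
                    yield (cr, cp)

    for x_r in range(n_r):
        for x_p in range(n_p):
            sep = x_r + x_p
            for cr, cp in pair_iter(x_r, x_p):
                prev = False
                for k in range(nt):
                    t = (k + 0.5) * dt
                    if contact.contact_type == 1:
                        lam, act = _oracle_state(cr, t, k, dt, *cwg)
                        elig = act and sep < lam
                    elif contact.contact_type == 2:
                        lam, act = _oracle_state(cp, t, k, dt, *cwg)
                        elig = act and sep < lam
                    else:
                        lr, ar = _oracle_state(cr, t, k, dt, *cwg)
                        lp, ap = _oracle_state(cp, t, k, dt, *cwg)
                        if config.contact.allow_cyt_cyt:
                            elig = ar and ap and sep < lr + lp
                        else:
                            elig = ar and ap and sep < min(lr, lp)
                    if elig and not prev:
                        counts[x_r, k] += 1
                    prev = elig
    return counts
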