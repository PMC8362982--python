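"""Contact eligibility and stochastic contact realization.

Eligibility between producing row ``x_p`` and receiving row ``x_r`` (separated
by ``x_p + x_r`` cell diameters) depends on the instantaneous cytoneme
lengths:

* type 1 — receiving cytonemes reach producing cell bodies:
  ``x_p + x_r < λ_r(t)``;
* type 2 — producing cytonemes reach receiving cell bodies:
  ``x_p + x_r < λ_p(t)``;
* type 3 — both sides extend cytonemes: a body contact when the separation is
  below ``min(λ_r, λ_p)`` and a cytoneme-cytoneme contact when it is between
  ``min(λ_r, λ_p)`` and ``λ_r + λ_p``.

An eligible pair fires one effective contact per eligibility episode once
eligibility has persisted for the contact time ``tc`` (measured as
``ceil(tc/dt)`` consecutive bins); it cannot fire again until eligibility
lapses.  Whether a contact actually transfers signal is decided by ψ: a
Bernoulli(μ) coin, a position-attenuated coin μ·(1 − x_r/range_max), or a
per-overlap-site binomial for the multiple-contacts variant Ψ(μ).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import Config, ConfigurationError
from .dynamics import (CytonemeTrajectory, STATIC, TRAPEZOIDAL, TRIANGULAR,
                       length_at)

__all__ = [
    "ContactEvent",
    "ContactField",
    "eligible_type1",
    "eligible_type2",
    "classify_type3",
    "psi_constant",
    "psi_position",
    "psi_multiple",
    "count_contacts",
]

BODY_CONTACT = "body-contact"
CYT_CYT = "cyt-cyt"


@dataclass(frozen=True)
class ContactEvent:
    x_r: int
    x_p: int
    t_bin: int
    n_contacts: int
    channel: str = BODY_CONTACT


@dataclass
class ContactField:
    """Contacts per receiving row per time bin for one replicate."""

    counts: np.ndarray            # (n_receiving_rows, n_bins) int
    dt: float
    events: list[ContactEvent] | None = field(default=None, repr=False)

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def total_per_row(self) -> np.ndarray:
        """Cumulative contacts N(x_r) over the whole run."""
        return self.counts.sum(axis=1)


# ---------------------------------------------------------------------------
# eligibility predicates
# ---------------------------------------------------------------------------

def eligible_type1(x_p: int, x_r: int, lambda_r: float) -> bool:
    """Receiving cytoneme of length ``lambda_r`` reaches producing row x_p."""
    return x_p + x_r < lambda_r


def eligible_type2(x_p: int, x_r: int, lambda_p: float) -> bool:
    """Producing cytoneme of length ``lambda_p`` reaches receiving row x_r."""
    return x_p + x_r < lambda_p


def classify_type3(x_p: int, x_r: int, lambda_r: float, lambda_p: float) -> str:
    """Classify a type-3 configuration as body contact, cyt-cyt, or none."""
    sep = x_p + x_r
    if sep < min(lambda_r, lambda_p):
        return BODY_CONTACT
    if sep < lambda_r + lambda_p:
        return CYT_CYT
    return "none"


# ---------------------------------------------------------------------------
# contact probability ψ
# ---------------------------------------------------------------------------

def psi_constant(mu: float, rng: np.random.Generator) -> int:
    """ψ(μ): Bernoulli(μ) — 1 when the eligible pair transfers signal."""
    return int(rng.random() < mu)


def psi_position(mu: float, x_r: int, range_max: float, rng: np.random.Generator) -> int:
    """ψ(μ, x): success probability attenuated linearly with cell position."""
    if range_max <= 0:
        raise ConfigurationError("range_max must be > 0")
    p = mu * max(0.0, 1.0 - x_r / range_max)
    return int(rng.random() < p)


def psi_multiple(mu: float, overlap_len: float, rng: np.random.Generator) -> int:
    """Ψ(μ): independent contacts along the overlapping membrane.

    The overlap (in cell diameters) is discretized into
    ``max(1, floor(overlap)+1)`` candidate sites, each succeeding with
    probability μ.
    """
    if overlap_len < 0:
        raise ConfigurationError("overlap length must be >= 0")
    k = max(1, int(math.floor(overlap_len)) + 1)
    return int(rng.binomial(k, mu))


# ---------------------------------------------------------------------------
# vectorized trajectory rasterization
# ---------------------------------------------------------------------------

def _rasterize(schedule: list[list[list[CytonemeTrajectory]]], times: np.ndarray,
               dt: float, cwg_triangular: bool, cwg_trapezoidal: bool):
    """Lengths and contact-active masks for every (row, slot) over time bins.

    The active mask encodes the contacting-while-growing (CWG) vs
    contacting-after-growth (CAG) window: under CWG a cytoneme can contact
    during its whole cycle; under CAG a triangular cytoneme contacts only in
    the bin containing its peak and a trapezoidal one only in the bins
    overlapping its plateau.  In those CAG bins the contact-relevant length is
    the maximum elongation λ_max (the cytoneme is fully extended when it
    contacts), which also keeps the window robust to time steps coarser than
    the peak passage.
    """
    n_rows = len(schedule)
    n_cyt = max((len(slots) for slots in schedule), default=0)
    nt = times.size
    L = np.zeros((n_rows, n_cyt, nt), dtype=float)
    A = np.zeros((n_rows, n_cyt, nt), dtype=bool)
    for row, slots in enumerate(schedule):
        for slot, cycles in enumerate(slots):
            for traj in cycles:
                if traj.behavior == STATIC:
                    L[row, slot, :] = traj.lambda_max
                    A[row, slot, :] = True
                    continue
                lo = np.searchsorted(times, traj.t_start, side="left")
                hi = np.searchsorted(times, traj.t_start + traj.lifetime, side="right")
                if hi > lo:
                    seg = length_at(traj, times[lo:hi])
                    L[row, slot, lo:hi] = np.maximum(L[row, slot, lo:hi], seg)
                cwg = cwg_triangular if traj.behavior == TRIANGULAR else cwg_trapezoidal
                if cwg:
                    if hi > lo:
                        A[row, slot, lo:hi] |= seg > 0
                elif traj.behavior == TRIANGULAR:
                    peak_bin = int(traj.t_peak_start // dt)
                    if 0 <= peak_bin < nt:
                        A[row, slot, peak_bin] = True
                        L[row, slot, peak_bin] = max(L[row, slot, peak_bin],
                                                     traj.lambda_max)
                else:
                    k_lo = max(0, int(traj.t_peak_start // dt))
                    k_hi = min(nt - 1, int(traj.t_peak_end // dt))
                    if k_hi >= k_lo:
                        A[row, slot, k_lo:k_hi + 1] = True
                        L[row, slot, k_lo:k_hi + 1] = np.maximum(
                            L[row, slot, k_lo:k_hi + 1], traj.lambda_max)
    return L, A


def _episodes(elig: np.ndarray):
    """Starts and lengths of True runs along axis 1 of a 2D boolean array."""
    m, nt = elig.shape
    padded = np.zeros((m, nt + 2), dtype=np.int8)
    padded[:, 1:-1] = elig
    d = np.diff(padded, axis=1)
    rows_s, starts = np.nonzero(d == 1)
    rows_e, ends = np.nonzero(d == -1)
    # row-major ordering pairs each start with its end
    return rows_s, starts, ends - starts


def _draw_counts(n_events: int, p: float, variant: str, k_sites: np.ndarray | None,
                 rng: np.random.Generator) -> np.ndarray:
    if n_events == 0:
        return np.zeros(0, dtype=int)
    if variant == "multiple":
        return rng.binomial(k_sites, p)
    return (rng.random(n_events) < p).astype(int)


# ---------------------------------------------------------------------------
# main engine
# ---------------------------------------------------------------------------

def count_contacts(recv_schedule, prod_schedule, config: Config,
                   rng: np.random.Generator, keep_events: bool = False) -> ContactField:
    """Realize stochastic contacts for one replicate.

    ``recv_schedule``/``prod_schedule`` are cycle schedules from
    :func:`cytograd.dynamics.generate_cycle_schedule` for the receiving and
    producing compartments (either may be ``None`` when the contact type does
    not use it).  Returns the contact field N(x_r, t_bin).
    """
    tissue, contact, sim, cyt = (config.tissue, config.contact,
                                 config.simulation, config.cytonemes)
    nt = sim.n_bins
    dt = sim.dt_s
    times = (np.arange(nt) + 0.5) * dt
    n_r, n_p = tissue.n_receiving_rows, tissue.n_producing_rows
    need = max(1, int(math.ceil(contact.tc_s / dt - 1e-12)))
    counts = np.zeros((n_r, nt), dtype=np.int64)
    events: list[ContactEvent] | None = [] if keep_events else None
    range_max = (contact.psi_range_max if contact.psi_range_max is not None
                 else float(n_r))

    ctype = contact.contact_type
    if ctype in (1, 3):
        if recv_schedule is None:
            raise ConfigurationError("contact type requires a receiving schedule")
        if len(recv_schedule) < n_r:
            raise ConfigurationError("receiving schedule shorter than N_R rows")
        L_r, A_r = _rasterize(recv_schedule, times, dt,
                              cyt.contact_while_growing_triangular,
                              cyt.contact_while_growing_trapezoidal)
    if ctype in (2, 3):
        if prod_schedule is None:
            raise ConfigurationError("contact type requires a producing schedule")
        if len(prod_schedule) < n_p:
            raise ConfigurationError("producing schedule shorter than N_P rows")
        L_p, A_p = _rasterize(prod_schedule, times, dt,
                              cyt.contact_while_growing_triangular,
                              cyt.contact_while_growing_trapezoidal)

    xp = np.arange(n_p)

    def _psi_p(x_r: int) -> float:
        if contact.psi_variant == "position":
            return contact.mu * max(0.0, 1.0 - x_r / range_max)
        return contact.mu

    for x_r in range(n_r):
        p_succ = _psi_p(x_r)
        if ctype == 1:
            lam = L_r[x_r][:, None, :]                     # (n_cyt, 1, nt)
            elig = A_r[x_r][:, None, :] & (lam > (x_r + xp)[None, :, None])
            m_shape = (lam.shape[0], n_p)
            flat = elig.reshape(-1, nt)
            rows, starts, lengths = _episodes(flat)
            ok = lengths >= need
            rows, bins = rows[ok], starts[ok] + need - 1
            x_p_of = rows % n_p
            k_sites = np.ones(rows.size, dtype=int) if contact.psi_variant == "multiple" else None
            n = _draw_counts(rows.size, p_succ, contact.psi_variant, k_sites, rng)
            np.add.at(counts[x_r], bins, n)
            if events is not None:
                for xpv, b, nv in zip(x_p_of, bins, n):
                    if nv > 0:
                        events.append(ContactEvent(x_r, int(xpv), int(b), int(nv)))
        elif ctype == 2:
            lam = L_p[:n_p]                                # (n_p, n_cyt, nt)
            elig = A_p[:n_p] & (lam > (x_r + xp)[:, None, None])
            flat = elig.reshape(-1, nt)
            rows, starts, lengths = _episodes(flat)
            ok = lengths >= need
            rows, bins = rows[ok], starts[ok] + need - 1
            n_cyt_p = lam.shape[1]
            x_p_of = rows // max(1, n_cyt_p)
            k_sites = np.ones(rows.size, dtype=int) if contact.psi_variant == "multiple" else None
            n = _draw_counts(rows.size, p_succ, contact.psi_variant, k_sites, rng)
            np.add.at(counts[x_r], bins, n)
            if events is not None:
                for xpv, b, nv in zip(x_p_of, bins, n):
                    if nv > 0:
                        events.append(ContactEvent(x_r, int(xpv), int(b), int(nv)))
        else:  # type 3
            lr = L_r[x_r]                                  # (n_cyt_r, nt)
            ar = A_r[x_r]
            lp = L_p[:n_p]                                 # (n_p, n_cyt_p, nt)
            ap = A_p[:n_p]
            sep = (x_r + xp).astype(float)                 # (n_p,)
            lr4 = lr[:, None, None, :]
            ar4 = ar[:, None, None, :]
            lp4 = lp[None, :, :, :]
            ap4 = ap[None, :, :, :]
            sep4 = sep[None, :, None, None]
            lam_min = np.minimum(lr4, lp4)
            both_active = ar4 & ap4
            if contact.allow_cyt_cyt:
                elig = both_active & (lr4 + lp4 > sep4)
            else:
                elig = both_active & (lam_min > sep4)
            n_cyt_r, _, n_cyt_p, _ = elig.shape[0], n_p, elig.shape[2], nt
            flat = elig.reshape(-1, nt)
            rows, starts, lengths = _episodes(flat)
            ok = lengths >= need
            rows, bins = rows[ok], starts[ok] + need - 1
            if rows.size:
                idx = np.unravel_index(rows, (n_cyt_r, n_p, n_cyt_p))
                lr_ev = lr[idx[0], bins]
                lp_ev = lp[idx[1], idx[2], bins]
                sep_ev = sep[idx[1]]
                if contact.psi_variant == "multiple":
                    overlap = np.clip(lr_ev + lp_ev - sep_ev, 0.0,
                                      np.minimum(lr_ev, lp_ev))
                    k_sites = np.maximum(1, np.floor(overlap).astype(int) + 1)
                else:
                    k_sites = None
                n = _draw_counts(rows.size, p_succ, contact.psi_variant, k_sites, rng)
                np.add.at(counts[x_r], bins, n)
                if events is not None:
                    channel = np.where(sep_ev < np.minimum(lr_ev, lp_ev),
                                       BODY_CONTACT, CYT_CYT)
                    for xpv, b, nv, ch in zip(idx[1], bins, n, channel):
                        if nv > 0:
                            events.append(ContactEvent(x_r, int(xpv), int(b),
                                                       int(nv), str(ch)))
    return ContactField(counts=counts, dt=dt, events=events)
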