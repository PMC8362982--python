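# Methods

## Model

The tissue is a 1D row of cells split at a compartment border into
morphogen-producing rows `x_p ∈ {0..N_P−1}` and receiving rows
`x_r ∈ {0..N_R−1}`, both counted outward from the border, so the distance
between a producing and a receiving cell is `x_p + x_r` cell diameters.
All lengths are normalized by the mean cell diameter φ (μm); time is in
seconds.

Morphogen transport is contact-mediated. Per receiving row the accumulated
signal follows

    u(x, t+dt) = u(x, t)·exp(−δ·dt) + α·ΔN(x, t→t+dt),   u(x, 0) = 0,

with α the amount transferred per contact (dimensionless; all comparisons
are on normalized shapes, so α is never fit to absolute fluorescence) and
δ = ln2/half-life the degradation rate. `N(x_r, t)` counts effective
contacts summed over producing rows.

### Cytoneme dynamics

Each cell carries `n_cyt` cytoneme slots. A slot runs consecutive life
cycles tiled over the simulation: per cycle the maximum length is re-drawn
(uniformly from a measured sample table when provided, otherwise from a
normal truncated to (0, ∞) with the given mean/SD), the behavior is
Bernoulli(fraction_triangular) — *triangular* (elongate at v_e, retract at
v_r) or *trapezoidal* (with a stationary plateau whose duration comes from
an empirical table or an exponential with the given mean) — and cycles are
separated by a configurable creation gap (default 0 s: immediate
re-initiation). Trajectories are evaluated analytically at arbitrary t, so
the time step affects only contact bookkeeping, never lengths. A *static*
mode holds every cytoneme at its drawn maximum for the whole run.

### Contact rules

Eligibility at a time bin (bin centers are the sample times):

* type 1: `x_p + x_r < λ_r(t)`; type 2: `x_p + x_r < λ_p(t)` (strict
  inequalities — the equations are taken as normative over the verbal
  "smaller than, or equal to");
* type 3 partitions into a body contact when the separation is below
  `min(λ_r, λ_p)` and a cytoneme-cytoneme contact up to `λ_r + λ_p`
  (cyt-cyt contacts can be disabled, which degrades type 3 to body contacts
  and is warned about).

**Contact windows.** With contacting-while-growing (CWG, the default) a
cytoneme can contact throughout its cycle. With contacting-after-growth
(CAG) a triangular cytoneme contacts only in the bin containing its peak
and a trapezoidal one only in the bins overlapping its plateau; in those
bins the contact-relevant length is λ_max (the cytoneme is fully extended
when it contacts), which also keeps the window robust to time steps coarser
than the peak passage.

**Persistence and refractoriness.** Eligibility must persist
`ceil(tc/dt)` consecutive bins before a pair/slot fires, and the pair then
stays silent until eligibility lapses — one effective contact per
eligibility episode. This makes contact counts independent of dt for
persistent geometries and prevents time-step inflation. A side effect worth
knowing: a marginal pair whose length sum dips below the separation
mid-cycle splits one episode into two, so an intermediate row can collect
slightly more contacts than row 0 (a few percent in reference runs).

**Contact probability ψ.** Eligible events succeed by one of three models:
ψ(μ), a Bernoulli(μ) coin; ψ(μ,x), Bernoulli(μ·max(0, 1−x_r/range_max)),
a linear positional attenuation (range_max defaults to N_R); Ψ(μ),
Binomial(k, μ) with k = max(1, floor(overlap)+1) candidate sites along the
overlapping membrane length `clamp(λ_r+λ_p−sep, 0, min(λ_r,λ_p))`. The
ψ(μ,x) and Ψ(μ) functional forms are this package's documented choices —
linear attenuation reproduces the faster, more linear decay expected of a
position-dependent contact probability, and per-cell-diameter overlap sites
are the natural discretization; tc applies per cytoneme pair, not per site.

### Ensembles, seeds, reproducibility

An ensemble runs `n_replicates` independent replicates; per-replicate
generators derive from the master seed via `numpy.random.SeedSequence.spawn`,
so results are bit-reproducible and parameter scans share replicate seeds
for variance reduction. Mean and SD are computed across replicates (a
single-replicate ensemble reports SD 0 with a warning). The canonical study
size is 2000 replicates; tests and examples scale down (20–400 replicates,
minutes of simulated time), sizes chosen to keep the suite fast while
leaving Monte-Carlo error well inside the asserted tolerances.

### FRAP

Photobleaching scales the accumulated signal by (1 − bleach_fraction) at
the bleach time; the transport machinery is unaffected (bleaching destroys
fluorophore, not cytonemes). By linearity the bleached trajectory equals
the unbleached one minus the bleached amount decaying at δ, which is how it
is computed. Recovery is reported relative to the fixed pre-bleach profile
(the experimental convention of normalizing to the pre-bleach maximum),
sampled every 45 s to mirror the acquisition cadence, averaged over rows
carrying ≥1% of the peak pre-bleach signal; the across-replicate SD
accompanies the mean. Note that relative to a *time-matched unbleached
control* the deficit can only decay at rate δ (~21% per 50 min for a
166-min half-life), so high recovery percentages on the experimental
timescale imply a gradient still being established — the histoblast
protocol therefore builds the gradient for 60 min, bleaches 85%, and
follows recovery for 50 min inside a 110-min signaling window.

## Parameters

| parameter | default | provenance |
|---|---|---|
| φ (wing disc / histoblast) | 3.05 / 4.37 μm | measured cell diameters |
| λ_r, λ_p (wing disc) | 11.8±4.1, 14.5±5.5 μm | measured cytoneme lengths |
| λ_r, λ_p (histoblast) | 7.3±2.5, 8.9±3.2 μm | **placeholder** (shorter than wing disc, source values unpublished here) |
| v_e, v_r | 0.1 μm/s | **placeholder** typical filopodial velocity |
| stationary time | exp(mean 60 s) | placeholder; empirical table preferred |
| fraction triangular | 0.5 | half/half mixes fit observed dynamics best |
| n_cyt | 4 | reference cytoneme density |
| N_P / N_R | 15 / 10 | reference tissue; gradient saturates beyond combined reach |
| contact type | 3 | both-sided contacts, the reference scenario |
| μ, tc | 1.0, 60 s | reference contact probability and contact time |
| α | 1 | contacts ↔ morphogen units; shape comparisons only |
| half-life | 166 min (Hh); 45 min (Dpp) | measured degradation |
| dt | 1 s | well below cycle timescales; halving dt moves ensemble means <1% |

λ_max is operationalized as mean + 1 SD throughout (the convention under
which 11.8+4.1 → 15.9 μm and 14.5+5.5 → 20 μm), and sample SDs use the
unbiased n−1 denominator (configurable). The gradient-range estimator adds
`source_rows` producing cells (default 2, the narrow Wg stripe) to the
reach λ_max,r + λ_max,p to convert it into a distance from the border.

## Diffusion-degradation reference

`∂u/∂t = D∂²u/∂x² − δu` on [0, L], Dirichlet u(0,t)=u0 at the source,
Neumann ∂u/∂x(L,t)=0 (morphogen cannot escape), u(x,0)=0. Crank–Nicolson
stepping with ghost-node mirroring at the far boundary; the first two steps
use backward Euler (Rannacher start-up) because the discontinuous initial
condition otherwise rings and transiently violates the maximum principle.
The steady state matches u0·cosh(k(L−x))/cosh(kL), k=√(δ/D), to <0.5% on a
400-point grid; `fit_diffusion_to_profile` grid-searches D against a
normalized profile using the direct steady-state solve.

## Intensity-profile protocol

Experimental (or synthetic) 1D profiles pass through: background
subtraction (mean over a designated inactive region, clipped at zero);
normalization by the mean of the top-3 intensities (reporter channel) or a
source-region mean (morphogen channel); origin alignment at the position of
the maximum first difference of the 3-point-smoothed reporter profile (a
rise that does not exceed 5× the median absolute difference is rejected as
noise); FRAP drift correction (I_roi−bg)/(I_control−bg). The synthetic
generator produces exponential-plus-background morphogen profiles with a
logistic reporter step and optional replicate SD envelopes.

## What the synthetic data does and does not emulate

Synthetic length tables are truncated-normal draws around the measured
means — they reproduce the location, spread and bounded support of measured
samples but not skew, measurement quantization, or any correlation between
length and phase times (phases are treated as independent). Synthetic
fluorescence profiles are noisy exponentials with a sharp reporter step —
they exercise the background/normalization/alignment pipeline but contain
no imaging artifacts (uneven illumination, z-projection bias). Passing
tests therefore validate the computational protocol, not the imaging
chain.

## Numerical choices and degenerate inputs

Strict inequalities at eligibility boundaries; exact ties (possible when
lengths are exact multiples of φ) count as ineligible. tc persistence is
`ceil(tc/dt)` bins; tc=0 fires on a single eligible bin. Zero-SD length
distributions, empty schedules (n_cyt=0), μ∈{0,1} and infinite half-life
(δ=0) are all exercised in the tests. Subgroup CVs flag zero-mean subgroups
as NaN. The canonical replicate vector is partitioned into 100 equal
subgroups in replicate order; a fixed subgroup size of 200 with a
proportional number of subgroups is available, and indivisible lengths are
rejected with a suggested scheme.

## Limitations

1D geometry only; no cytoneme orientation/guidance, no vesicular transport
along cytonemes, no receptor binding kinetics. Elongation/retraction
velocities and histoblast length statistics are placeholders pending
measured values. The extent of a stochastic gradient ("last row with
nonzero mean contacts") is an extreme-value statistic: it is stable for
bounded (measured-sample) length inputs but grows slowly with ensemble size
under unbounded truncated-normal sampling.
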