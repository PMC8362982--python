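"""Fluorescence intensity-profile protocols and synthetic profile generation.

Implements the measurement protocol applied to experimental 1D fluorescence
profiles before any comparison with simulations: background subtraction over
an inactive region, normalization (mean of the top-3 intensities for a
reporter channel, or a source-region mean for the morphogen channel), origin
alignment at the sharp rise of the reporter at the compartment border, and
the FRAP control normalization (I_roi − bg)/(I_control − bg).  A synthetic
generator produces exponential-plus-background profiles with a reporter step
so the whole pipeline is testable without imaging data.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, LengthStats

__all__ = [
    "IntensityProfile",
    "GradientRange",
    "subtract_background",
    "normalize_profile",
    "find_origin",
    "align_origin",
    "frap_normalize",
    "synthesize_profile",
    "synthesize_frap_series",
    "estimate_gradient_range",
]


@dataclass(frozen=True)
class IntensityProfile:
    """A 1D fluorescence profile on a uniform position grid."""

    position_um: np.ndarray
    intensity: np.ndarray
    sd: np.ndarray | None = None
    background: float = 0.0
    origin_offset_um: float = 0.0
    channel: str = "morphogen"      # morphogen | reporter | control

    def __post_init__(self) -> None:
        pos = np.asarray(self.position_um, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if pos.size != inten.size:
            raise ConfigurationError("position and intensity lengths differ")
        if pos.size >= 2:
            steps = np.diff(pos)
            if (steps <= 0).any():
                raise ConfigurationError("positions must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ConfigurationError("positions must form a uniform grid")
        if self.background < 0:
            raise ConfigurationError("background must be >= 0")
        object.__setattr__(self, "position_um", pos)
        object.__setattr__(self, "intensity", inten)
        if self.sd is not None:
            sd = np.asarray(self.sd, dtype=float)
            if sd.size != pos.size:
                raise ConfigurationError("SD envelope length mismatch")
            object.__setattr__(self, "sd", sd)

    @property
    def dx(self) -> float:
        return float(self.position_um[1] - self.position_um[0])

    def in_cell_diameters(self, phi: float) -> "IntensityProfile":
        return dataclasses.replace(self, position_um=self.position_um / phi)


def subtract_background(profile: IntensityProfile,
                        inactive_region: tuple[float, float]) -> IntensityProfile:
    """Subtract the mean signal over a region where the reporter is inactive.

    Intensities are clipped at zero; the estimated background is stored on the
    returned profile.
    """
    lo, hi = inactive_region
    pos = profile.position_um
    if lo < pos[0] - 1e-9 or hi > pos[-1] + 1e-9 or hi <= lo:
        raise ConfigurationError("inactive region outside the profile span")
    mask = (pos >= lo) & (pos <= hi)
    if not mask.any():
        raise ConfigurationError("inactive region contains no samples")
    bg = float(profile.intensity[mask].mean())
    return dataclasses.replace(profile,
                               intensity=np.clip(profile.intensity - bg, 0.0, None),
                               background=bg)


def normalize_profile(profile: IntensityProfile, mode: str = "top_k_max",
                      k: int = 3, region: tuple[float, float] | None = None
                      ) -> IntensityProfile:
    """Scale intensities to a unit reference.

    ``top_k_max`` divides by the mean of the ``k`` largest values (reporter
    convention, k=3); ``region_mean`` divides by the mean over a designated
    source region (morphogen convention).
    """
    inten = profile.intensity
    if inten.max() <= 0:
        raise ConfigurationError("cannot normalize an all-zero profile")
    if mode == "top_k_max":
        ref = float(np.sort(inten)[-k:].mean())
    elif mode == "region_mean":
        if region is None:
            raise ConfigurationError("region_mean normalization needs a region")
        lo, hi = region
        mask = (profile.position_um >= lo) & (profile.position_um <= hi)
        if not mask.any():
            raise ConfigurationError("normalization region contains no samples")
        ref = float(inten[mask].mean())
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    if ref <= 0:
        raise ConfigurationError("normalization reference is non-positive")
    sd = profile.sd / ref if profile.sd is not None else None
    return dataclasses.replace(profile, intensity=inten / ref, sd=sd)


def find_origin(reporter: IntensityProfile) -> float:
    """Position of the sharp reporter rise (compartment border).

    The profile is smoothed with a 3-point moving average and the origin is
    the position of the maximum first difference.  A profile whose largest
    rise does not stand out from the noise floor (a flat or uniformly rising
    profile) raises an error.
    """
    y = reporter.intensity
    if y.size < 4:
        raise ConfigurationError("reporter profile too short for edge detection")
    smooth = np.convolve(y, np.ones(3) / 3.0, mode="valid")  # positions 1..n-2
    d = np.diff(smooth)
    if d.size == 0 or d.max() <= 0:
        raise ConfigurationError("reporter profile has no rising edge")
    noise = np.median(np.abs(d))
    if noise > 0 and d.max() < 5.0 * noise:
        raise ConfigurationError("reporter rise does not exceed the noise floor")
    j = int(np.argmax(d))
    return float(reporter.position_um[j + 2])


def align_origin(reporter: IntensityProfile,
                 others: tuple[IntensityProfile, ...] = ()
                 ) -> tuple[float, list[IntensityProfile]]:
    """Locate the border on the reporter channel and shift all channels to it.

    Returns the origin position (in the input frame) and the shifted profiles
    (reporter first), whose positions now place the origin at x = 0.
    """
    origin = find_origin(reporter)
    shifted = []
    for prof in (reporter, *others):
        shifted.append(dataclasses.replace(
            prof, position_um=prof.position_um - origin,
            origin_offset_um=origin))
    return origin, shifted


def frap_normalize(i_roi, bg, i_control):
    """Photobleaching-drift-corrected recovery: (I_roi − bg)/(I_control − bg)."""
    i_roi = np.asarray(i_roi, dtype=float)
    i_control = np.asarray(i_control, dtype=float)
    if np.any(i_control <= bg):
        raise ConfigurationError("control intensity must exceed the background")
    out = (i_roi - bg) / (i_control - bg)
    return float(out) if out.ndim == 0 else out


def synthesize_profile(amplitude: float, decay_length_um: float,
                       background: float, noise_sd: float,
                       step_position_um: float, rng: np.random.Generator,
                       x_max_um: float = 90.0, dx_um: float = 0.5,
                       n_replicates: int = 1
                       ) -> tuple[IntensityProfile, IntensityProfile]:
    """Synthetic morphogen + reporter channel pair.

    The morphogen channel is ``amplitude·exp(−x/decay) + background`` plus
    Gaussian noise; the reporter channel adds a sharp logistic rise at
    ``step_position_um``.  With ``n_replicates > 1`` the morphogen profile
    carries the across-replicate SD envelope.
    """
    if decay_length_um <= 0:
        raise ConfigurationError("decay length must be > 0")
    x = np.arange(0.0, x_max_um + 0.5 * dx_um, dx_um)
    signal = amplitude * np.exp(-np.clip(x - step_position_um, 0.0, None)
                                / decay_length_um)
    signal[x < step_position_um] = amplitude
    reps = signal[None, :] + background + rng.normal(
        0.0, noise_sd, size=(n_replicates, x.size))
    morph = IntensityProfile(
        position_um=x, intensity=reps.mean(axis=0),
        sd=reps.std(axis=0, ddof=1) if n_replicates > 1 else None,
        channel="morphogen")
    step = amplitude / (1.0 + np.exp(-(x - step_position_um) / (1.5 * dx_um)))
    rep_int = step + background + rng.normal(0.0, noise_sd, size=x.size)
    reporter = IntensityProfile(position_um=x, intensity=rep_int,
                                channel="reporter")
    return morph, reporter


def synthesize_frap_series(n_points: int, recovery_rate: float,
                           acquisition_bleach: float, background: float,
                           rng: np.random.Generator, dt_s: float = 45.0
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """FRAP time series with acquisition-photobleaching drift on both channels.

    Returns (times, I_roi, I_control, background).  The true ROI recovery is
    ``1 − exp(−recovery_rate·t)`` of the control level; both measured channels
    drift downward by the per-frame acquisition bleaching factor, which
    :func:`frap_normalize` must cancel.
    """
    t = np.arange(n_points) * dt_s
    drift = (1.0 - acquisition_bleach) ** np.arange(n_points)
    control_level = 100.0
    true_recovery = 1.0 - np.exp(-recovery_rate * t)
    i_control = background + control_level * drift + rng.normal(0, 0.0, n_points)
    i_roi = background + control_level * true_recovery * drift
    return t, i_roi, i_control, background


@dataclass(frozen=True)
class GradientRange:
    """Analytic gradient extent from maximum cytoneme lengths."""

    reach_um: float              # λ_max,r + λ_max,p, from the last producing cell
    extent_from_border_um: float # reach + source_rows·phi
    n_cells: int                 # rounded extent in cell diameters


def estimate_gradient_range(stats_r: LengthStats, stats_p: LengthStats,
                            phi: float, source_rows: int = 2) -> GradientRange:
    """Maximum gradient range from the contact-reach condition.

    The farthest receiving row satisfying the type-3 condition
    ``x_p + x_r < λ_r + λ_p`` lies ``λ_max,r + λ_max,p`` (λ_max = mean + SD)
    beyond the last producing cell; adding the producing stripe width
    (``source_rows`` cells) gives the extent from the compartment border.
    """
    if phi <= 0:
        raise ConfigurationError("phi must be > 0")
    if source_rows < 0:
        raise ConfigurationError("source_rows must be >= 0")
    reach = stats_r.lambda_max_um + stats_p.lambda_max_um
    extent = reach + source_rows * phi
    return GradientRange(reach_um=reach, extent_from_border_um=extent,
                         n_cells=int(round(extent / phi)))
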