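"""Ensemble summaries: CV subgrouping, rank-sum matrices, shape comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .config import ConfigurationError
from .simulate import GradientResult

__all__ = [
    "CaseComparison",
    "FitReport",
    "ShapeSummary",
    "cv_subgroups",
    "wilcoxon_matrix",
    "significance_code",
    "normalized_shape",
    "compare_to_experiment",
    "plot_significance_matrix",
]

_CODES = (
    (0.0001, "****"),
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)


def significance_code(p: float) -> str:
    for threshold, code in _CODES:
        if p < threshold:
            return code
    return "n.s"


def cv_subgroups(values, n_subgroups: int = 100,
                 subgroup_size: int | None = None) -> np.ndarray:
    """Coefficients of variation over consecutive subgroups of replicates.

    By default the replicate vector is partitioned, in replicate order, into
    100 equal subgroups (the canonical 2000 replicates give 100 CVs of 20
    replicates each).  Passing ``subgroup_size`` instead fixes the size and
    derives a proportional number of subgroups.  Subgroups with zero mean
    yield NaN (flagged).
    """
    v = np.asarray(values, dtype=float)
    if subgroup_size is not None:
        if v.size == 0 or v.size % subgroup_size != 0:
            n_fit = max(1, v.size // subgroup_size)
            raise ConfigurationError(
                f"{v.size} replicates cannot be split into subgroups of "
                f"{subgroup_size}; try {n_fit}x{subgroup_size} with "
                f"{n_fit * subgroup_size} replicates")
    else:
        if v.size == 0 or v.size % n_subgroups != 0:
            raise ConfigurationError(
                f"{v.size} replicates cannot be split into {n_subgroups} "
                f"equal subgroups")
        subgroup_size = v.size // n_subgroups
    groups = v.reshape(-1, subgroup_size)
    means = groups.mean(axis=1)
    sds = groups.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(means != 0, sds / means, np.nan)
    if np.isnan(cv).all():
        warnings.warn("all subgroups have zero mean; CVs undefined", UserWarning,
                      stacklevel=2)
    return cv


@dataclass
class CaseComparison:
    """Pairwise rank-sum comparison across simulation cases."""

    labels: list[str]
    p_values: np.ndarray            # (k, k), symmetric, unit diagonal
    codes: list[list[str]]

    def code(self, a: str, b: str) -> str:
        i, j = self.labels.index(a), self.labels.index(b)
        return self.codes[i][j]


def wilcoxon_matrix(samples: dict[str, np.ndarray]) -> CaseComparison:
    """Two-sided Wilcoxon rank-sum p-values for every pair of cases.

    Ties are handled by the tie-corrected normal approximation.  Codes follow
    the n.s/*/**/***/**** convention at 0.05/0.01/0.001/0.0001.
    """
    labels = list(samples)
    if len(labels) < 2:
        raise ConfigurationError("need at least two cases to compare")
    arrays = {}
    for k, v in samples.items():
        a = np.asarray(v, dtype=float)
        if a.size < 2:
            raise ConfigurationError(f"case {k!r} needs at least 2 observations")
        arrays[k] = a
    k = len(labels)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[labels[i]], arrays[labels[j]]
            if np.array_equal(a, b):
                pij = 1.0
            else:
                pij = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                             method="asymptotic").pvalue)
            p[i, j] = p[j, i] = pij
    codes = [[significance_code(p[i, j]) if i != j else "n.s" for j in range(k)]
             for i in range(k)]
    return CaseComparison(labels=labels, p_values=p, codes=codes)


@dataclass
class ShapeSummary:
    """Gradient shape: per-row values scaled so the maximum is 1."""

    rows: np.ndarray                 # receiving row indices
    mean_shape: np.ndarray           # normalized ensemble mean, max == 1
    per_replicate: np.ndarray | None # (n_rep, n_rows) normalized replicates
    scaling_coefficient: np.ndarray  # per-row mean of normalized values
    decay_coefficient: float | None  # exponential decay rate fit (1/row)


def normalized_shape(result: GradientResult, mode: str = "ensemble_mean") -> ShapeSummary:
    """Normalize the gradient to its maximum to compare shapes across cases.

    ``mode="ensemble_mean"`` (default) divides by the maximum of the ensemble
    mean; ``mode="per_replicate"`` divides each replicate by its own maximum.
    """
    mean = result.mean
    if mean.max() <= 0:
        raise ConfigurationError("all-zero gradient cannot be normalized")
    rows = np.arange(mean.size)
    if mode == "ensemble_mean":
        per_rep = result.u_final / mean.max()
    elif mode == "per_replicate":
        rep_max = result.u_final.max(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            per_rep = np.where(rep_max > 0, result.u_final / rep_max, 0.0)
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    mean_shape = mean / mean.max()
    scaling = per_rep.mean(axis=0)
    decay = None
    pos = mean_shape > 1e-3
    if pos.sum() >= 3:
        slope = np.polyfit(rows[pos], np.log(mean_shape[pos]), 1)[0]
        if slope < 0:
            decay = float(-slope)
    return ShapeSummary(rows=rows, mean_shape=mean_shape, per_replicate=per_rep,
                        scaling_coefficient=scaling, decay_coefficient=decay)


@dataclass
class FitReport:
    positions: np.ndarray
    model: np.ndarray
    experimental_mean: np.ndarray
    experimental_sd: np.ndarray
    residuals: np.ndarray
    fraction_within_sd: float


def compare_to_experiment(result: GradientResult, profile) -> FitReport:
    """Fraction of receiving rows where the model falls inside the
    experimental SD envelope.

    The model is normalized to its own maximum; the profile (positions in cell
    diameters with an SD envelope) is linearly resampled onto the model rows
    when the grids differ (with a warning).
    """
    model = result.mean
    if model.max() <= 0:
        raise ConfigurationError("all-zero model gradient")
    model = model / model.max()
    rows = np.arange(model.size, dtype=float)
    pos = np.asarray(profile.position_um, dtype=float)
    exp_mean = np.asarray(profile.intensity, dtype=float)
    if profile.sd is None:
        raise ConfigurationError("experimental profile needs an SD envelope")
    exp_sd = np.asarray(profile.sd, dtype=float)
    if pos.size != rows.size or not np.allclose(pos, rows):
        warnings.warn("experimental grid differs from model rows; resampling",
                      UserWarning, stacklevel=2)
        exp_mean = np.interp(rows, pos, exp_mean)
        exp_sd = np.interp(rows, pos, exp_sd)
    residuals = model - exp_mean
    within = np.abs(residuals) <= exp_sd
    return FitReport(positions=rows, model=model, experimental_mean=exp_mean,
                     experimental_sd=exp_sd, residuals=residuals,
                     fraction_within_sd=float(within.mean()))


def plot_significance_matrix(comparison: CaseComparison, path: str) -> None:
    """Minimal green-coded significance matrix figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    k = len(comparison.labels)
    levels = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            levels[i, j] = len(comparison.codes[i][j].replace("n.s", ""))
    fig, ax = plt.subplots(figsize=(1.2 * k + 2, 1.2 * k + 1))
    ax.imshow(levels, cmap="Greens", vmin=0, vmax=4)
    ax.set_xticks(range(k), comparison.labels, rotation=45, ha="right")
    ax.set_yticks(range(k), comparison.labels)
    for i in range(k):
        for j in range(k):
            ax.text(j, i, comparison.codes[i][j], ha="center", va="center",
                    fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
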