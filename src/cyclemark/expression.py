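"""Count filtering, precision-weighted log transformation, mean profiles.

The transform follows the voom recipe: log2 counts-per-million with
pseudo-counts (0.5 on the count, 1 on the library size), a lowess fit
of sqrt(residual standard deviation) against mean log count across
genes, and per-observation precision weights equal to the predicted
standard deviation (on the fitted count scale) to the power -4, with
the trend clipped to the fitted range at the extremes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .design import TimeCourseDesign


def filter_zero_count(counts: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly the genes with all counts > 0 across all samples.

    Genes with a zero in any profile would otherwise dominate the PLS
    model with on/off patterns.  Gene order is preserved.
    """
    if counts.empty:
        return counts.copy()
    return counts.loc[(counts > 0).all(axis=1)].copy()


@dataclass
class WeightedLogExpression:
    """log2-CPM values with per-observation precision weights."""

    values: pd.DataFrame   # genes x samples, log2 CPM
    weights: pd.DataFrame  # same shape, strictly positive
    trend_x: np.ndarray    # mean log2 count knots of the lowess fit
    trend_y: np.ndarray    # fitted sqrt-sd at the knots

    def __post_init__(self) -> None:
        if self.values.shape != self.weights.shape:
            raise ValueError("values and weights must have the same shape")


def voom_transform(counts: pd.DataFrame, smoother_span: float = 0.5,
                   ) -> WeightedLogExpression:
    """Transform counts to precision-weighted log2 CPM.

    value(g, s) = log2((count + 0.5) / (libsize + 1) * 1e6).  Residual
    standard deviations are taken about each gene's mean (the design
    here is a single synchronized population, so no covariate model is
    imposed at this stage).
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate residual sd")
    lib = counts.sum(axis=0).to_numpy(dtype=float)
    c = counts.to_numpy(dtype=float)
    values = np.log2((c + 0.5) / (lib + 1.0)[None, :] * 1e6)

    gene_sd = values.std(axis=1, ddof=1)
    sqrt_sd = np.sqrt(gene_sd)
    mean_log_count = np.log2(c + 0.5).mean(axis=1)

    if np.ptp(mean_log_count) == 0:  # degenerate: flat trend
        trend_x = np.array([mean_log_count[0] - 0.5, mean_log_count[0] + 0.5])
        trend_y = np.full(2, max(float(np.mean(sqrt_sd)), 1e-6))
    else:
        fit = lowess(sqrt_sd, mean_log_count, frac=smoother_span,
                     return_sorted=True)
        trend_x, trend_y = fit[:, 0], np.maximum(fit[:, 1], 1e-6)

    # predicted sqrt-sd at each observation's fitted log-count, clipped
    # to the trend's range at the extremes
    obs_log_count = values + np.log2((lib + 1.0) / 1e6)[None, :]
    pred = np.interp(obs_log_count, trend_x, trend_y,
                     left=trend_y[0], right=trend_y[-1])
    weights = pred ** -4.0

    return WeightedLogExpression(
        values=pd.DataFrame(values, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(weights, index=counts.index, columns=counts.columns),
        trend_x=trend_x, trend_y=trend_y)


def mean_profile(values: pd.DataFrame, design: TimeCourseDesign,
                 assay: str | None = None) -> pd.DataFrame:
    """Per-gene mean over replicates at each time point.

    Samples excluded for ``assay`` are skipped; a time point whose
    replicates are all excluded (or missing) yields NaN, never zero.
    Returns genes x time-points (columns are hours, ascending).
    """
    kept = [s for s in design.kept_samples(assay) if s in values.columns]
    cols = {t: [s for s in kept if design.hours_of(s) == t]
            for t in design.time_points_hours}
    out = pd.DataFrame(index=values.index,
                       columns=list(design.time_points_hours), dtype=float)
    for t, samples in cols.items():
        out[t] = values[samples].mean(axis=1) if samples else np.nan
    return out
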