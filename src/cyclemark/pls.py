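"""Cell-cycle gene detection by PLS regression on FACS phase fractions.

The FACS matrix (per-sample fractions of cells in G1/S/G2M) is used
directly as the multivariate response; genes whose expression tracks it
through the time course score high on VIP (variable importance in
projection).  Significance comes from a design-respecting permutation
test: time-point labels are shuffled within each replicate, the
per-gene association statistic is refit, and observed values are
compared with their permutation nulls.  Benjamini-Hochberg control at
q <= 0.05 defines the cyclic gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .design import TimeCourseDesign, sample_id
from .stats import bh_fdr


@dataclass
class PlsResult:
    n_components: int
    vip: pd.Series                      # per-gene importance, mean(VIP^2) = 1
    x_weights: np.ndarray               # genes x components (unit columns)
    y_loadings: np.ndarray              # responses x components
    p_values: pd.Series | None = None
    q_values: pd.Series | None = None
    q_threshold: float = 0.05
    cyclic_genes: list[str] = field(default_factory=list)


def _prepare(X: pd.DataFrame, Y: pd.DataFrame,
             gene_weights: pd.Series | None):
    """Center (and precision-weight) X, center Y; split off constant genes."""
    Xc = X.to_numpy(dtype=float)
    Xc = Xc - Xc.mean(axis=0)
    if gene_weights is not None:
        w = gene_weights.reindex(X.columns).to_numpy(dtype=float)
        Xc = Xc * (w / w.mean())[None, :]
    Yc = Y.to_numpy(dtype=float)
    Yc = Yc - Yc.mean(axis=0)
    keep = Xc.std(axis=0) > 0
    return Xc, Yc, keep


def _vip(pls: PLSRegression) -> np.ndarray:
    """VIP from X-weights and per-component explained Y-variance."""
    W = pls.x_weights_                      # p x A, unit columns
    T = pls.x_scores_                       # n x A
    Q = pls.y_loadings_                     # q x A
    ss = (Q ** 2).sum(axis=0) * (T ** 2).sum(axis=0)   # per-component Y SS
    p = W.shape[0]
    wnorm2 = (W ** 2) / np.maximum((W ** 2).sum(axis=0), 1e-300)[None, :]
    return np.sqrt(p * (wnorm2 @ ss) / ss.sum())


def fit_pls(X: pd.DataFrame, Y: pd.DataFrame, n_components: int = 3,
            gene_weights: pd.Series | None = None) -> PlsResult:
    """Fit a PLS2 model of genes (X) against phase fractions (Y).

    Rows of X and Y must be aligned on the same samples.  X columns are
    centered and, when ``gene_weights`` (mean precision weight per
    gene) is given, scaled by the normalized weight.  Constant gene
    columns get VIP 0.
    """
    if list(X.index) != list(Y.index):
        raise ValueError("X and Y must be indexed by the same samples")
    if n_components > min(X.shape[0] - 1, X.shape[1]):
        raise ValueError("n_components exceeds the data rank")
    Xc, Yc, keep = _prepare(X, Y, gene_weights)
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        pls.fit(Xc[:, keep], Yc)
    vip = np.zeros(X.shape[1])
    vip[keep] = _vip(pls)
    return PlsResult(n_components=n_components,
                     vip=pd.Series(vip, index=X.columns, name="VIP"),
                     x_weights=pls.x_weights_, y_loadings=pls.y_loadings_)


def _permute_rows(rows: np.ndarray, n_times: int, rng) -> np.ndarray:
    """Row order permuting time points independently within each replicate."""
    out = np.empty(rows.size, dtype=int)
    for r in range(rows.shape[0]):
        out[rows[r]] = rows[r][rng.permutation(n_times)]
    return out


def _replicate_time_rows(samples, design: TimeCourseDesign) -> np.ndarray:
    """Row positions as a (replicates x time points) matrix."""
    pos = {s: i for i, s in enumerate(samples)}
    mat = np.empty((len(design.replicates), len(design.time_points_hours)),
                   dtype=int)
    for i, r in enumerate(design.replicates):
        for j, t in enumerate(design.time_points_hours):
            mat[i, j] = pos[sample_id(r, t)]
    return mat


def _r2_statistic(Xc: np.ndarray, weights_sqrt: np.ndarray | None):
    """Per-gene R^2 onto the rank-truncated column span of a response.

    Returns a callable null_stat(Yc) -> per-gene R^2.  With per-
    observation precision weights the projection is the weighted least
    squares fit of each gene's profile on the response columns.  The
    response span is truncated at its numerical rank (a row-normalized
    fraction matrix is rank-deficient after centering), so noise cannot
    leak in through a spurious dimension.
    """
    if weights_sqrt is None:
        denom = (Xc ** 2).sum(axis=0)

        def stat(Yc: np.ndarray) -> np.ndarray:
            U, s, _ = np.linalg.svd(Yc, full_matrices=False)
            Q = U[:, s > s[0] * 1e-8]
            proj = Q.T @ Xc
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = (proj ** 2).sum(axis=0) / denom
            return np.where(denom > 0, r2, 0.0)
    else:
        Xw = weights_sqrt * Xc
        denom = (Xw ** 2).sum(axis=0)

        def stat(Yc: np.ndarray) -> np.ndarray:
            A = weights_sqrt.T[:, :, None] * Yc[None, :, :]  # genes x n x q
            U, s, _ = np.linalg.svd(A, full_matrices=False)
            mask = s > s[:, :1] * 1e-8
            proj = np.einsum("gik,gi->gk", U, Xw.T) * mask
            with np.errstate(invalid="ignore", divide="ignore"):
                r2 = (proj ** 2).sum(axis=1) / denom
            return np.where(denom > 0, r2, 0.0)

    return stat


def gene_significance(X: pd.DataFrame, Y: pd.DataFrame,
                      design: TimeCourseDesign, n_components: int = 3,
                      n_perm: int = 999, seed: int = 0,
                      q_threshold: float = 0.05,
                      weights: pd.DataFrame | None = None,
                      statistic: str = "r2") -> PlsResult:
    """Permutation p-values and BH q-values for cell-cycle association.

    The null permutes the time-point order of Y independently within
    each replicate (samples within a replicate are exchangeable under
    a gene's null of no time effect), refits the statistic, and counts
    exceedances: p = (1 + #{null >= observed}) / (1 + n_perm), ties
    counted as exceedances (conservative).

    ``statistic`` selects the permuted quantity:

    - ``"r2"`` (default): each gene's precision-weighted R^2 onto the
      rank-truncated span of the centered FACS matrix — an absolute,
      per-gene measure of how much of the profile the phase fractions
      explain.
    - ``"vip"``: the PLS VIP score.  VIP is normalized across genes,
      which couples each gene's null to the rest of the matrix and
      costs power; it is kept for comparison.

    ``weights`` are per-observation precision weights (genes x samples,
    as produced by the voom transform); they sharpen the R^2 statistic
    and set the column weighting of the reported PLS fit.
    """
    if n_perm < 99:
        raise ValueError("n_perm < 99 gives too little resolution for q <= 0.05")
    gene_weights = weights.mean(axis=1) if weights is not None else None
    res = fit_pls(X, Y, n_components=n_components, gene_weights=gene_weights)

    rows = _replicate_time_rows(X.index, design)
    n_times = rows.shape[1]
    Xc, Yc, keep = _prepare(X, Y, None)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 606]))
    exceed = np.zeros(X.shape[1])

    if statistic == "r2":
        wsq = None
        if weights is not None:
            wsq = np.sqrt(weights.loc[X.columns, X.index].to_numpy(dtype=float).T)
        stat = _r2_statistic(Xc, wsq)
        obs = stat(Yc)
        for _ in range(n_perm):
            Yp = Yc[_permute_rows(rows, n_times, rng)]
            Yp = Yp - Yp.mean(axis=0)
            exceed += stat(Yp) >= obs
    elif statistic == "vip":
        obs = res.vip.to_numpy()
        Xf, _, keep = _prepare(X, Y, gene_weights)
        pls = PLSRegression(n_components=n_components, scale=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for _ in range(n_perm):
                Yp = Yc[_permute_rows(rows, n_times, rng)]
                Yp = Yp - Yp.mean(axis=0)
                pls.fit(Xf[:, keep], Yp)
                null_vip = np.zeros(X.shape[1])
                null_vip[keep] = _vip(pls)
                exceed += null_vip >= obs
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    p = (1.0 + exceed) / (1.0 + n_perm)
    q = bh_fdr(p)
    p_ser = pd.Series(p, index=X.columns, name="p")
    q_ser = pd.Series(q, index=X.columns, name="q")
    res.p_values = p_ser
    res.q_values = q_ser
    res.q_threshold = q_threshold
    res.cyclic_genes = list(q_ser.index[q_ser <= q_threshold])
    return res


@dataclass
class ReferenceSets:
    """Non-cyclic comparison sets split at a bimodal expression boundary."""

    high: list[str]
    low: list[str]
    floor: float          # minimum mean expression among cyclic genes
    split_point: float    # expression at which the two components cross


def define_reference_sets(mean_expression: pd.Series, cyclic_set,
                          seed: int = 0) -> ReferenceSets:
    """Split eligible non-cyclic genes into high/low expression sets.

    Eligible genes are non-cyclic genes whose mean expression is at
    least the lowest cyclic gene's mean.  A two-component Gaussian
    mixture (10 EM restarts, best likelihood kept) on their mean log
    expression defines the split; assignment is by posterior >= 0.5.
    A degenerate mixture (effectively one component) yields a single
    high set with a warning.
    """
    cyclic_set = [g for g in cyclic_set if g in mean_expression.index]
    if not cyclic_set:
        raise ValueError("empty cyclic set")
    floor = float(mean_expression.loc[cyclic_set].min())
    eligible = mean_expression.drop(index=cyclic_set)
    eligible = eligible[eligible >= floor]
    if len(eligible) < 10:
        raise ValueError(f"only {len(eligible)} eligible genes (< 10)")
    x = eligible.to_numpy(dtype=float).reshape(-1, 1)
    if np.ptp(x) == 0:
        warnings.warn("degenerate expression distribution; single reference set")
        return ReferenceSets(high=list(eligible.index), low=[], floor=floor,
                             split_point=float(x[0, 0]))
    gm = GaussianMixture(n_components=2, n_init=10, random_state=seed).fit(x)
    means = gm.means_.ravel()
    hi_comp = int(np.argmax(means))
    post_hi = gm.predict_proba(x)[:, hi_comp]
    high = list(eligible.index[post_hi >= 0.5])
    low = list(eligible.index[post_hi < 0.5])
    if not low or not high or abs(means[0] - means[1]) < 1e-6:
        warnings.warn("mixture collapsed to one component; single reference set")
        return ReferenceSets(high=list(eligible.index), low=[], floor=floor,
                             split_point=float(means.mean()))
    grid = np.linspace(means.min(), means.max(), 2001).reshape(-1, 1)
    pg = gm.predict_proba(grid)[:, hi_comp]
    split = float(grid[np.argmin(np.abs(pg - 0.5)), 0])
    return ReferenceSets(high=high, low=low, floor=floor, split_point=split)
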