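"""RNA-ChIP correlation through the cycle: classification and set tests.

Per gene and antibody, RNA expression and TSS ChIP signal are paired
sample-by-sample (replicate x time point, exclusions dropped pairwise)
and Spearman-correlated.  Correlations are classed high (rho > 0.2),
low (rho < -0.2) or middle; the joint Pol II / H3K4me3 classes place
each cyclic gene into one of five groups; set-level tests compare
cyclic genes against the non-cyclic high/low reference sets; cyclic
lncRNAs with high Pol II or H3K4me3 correlation are the ranked
candidate list.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .design import TimeCourseDesign
from .stats import (bonferroni, one_sample_t, one_way_anova, spearman_rho,
                    welch_t)

HIGH_THRESHOLD = 0.2
LOW_THRESHOLD = -0.2
MIN_PAIRS = 4

GROUP_LABELS = ("both_high", "polII_only_high", "K4_only_high",
                "middle", "both_low")


def correlate_rna_chip(rna_values: pd.DataFrame, chip_values: pd.DataFrame,
                       design: TimeCourseDesign, antibody: str,
                       rna_assay: str | None = None) -> pd.DataFrame:
    """Per-gene Spearman rho between RNA and ChIP sample profiles.

    Pairs are individual samples (not per-time-point means); samples
    excluded for either assay, or missing/NaN in either matrix, are
    dropped pairwise.  Genes with fewer than 4 complete pairs, or a
    constant profile, get a missing rho.

    Returns a DataFrame indexed by gene with columns antibody, rho,
    n_pairs, and class (high/middle/low, NaN-safe).
    """
    kept = [s for s in design.kept_samples(antibody)
            if s in design.kept_samples(rna_assay)
            and s in rna_values.columns and s in chip_values.columns]
    genes = rna_values.index.intersection(chip_values.index)
    rna = rna_values.loc[genes, kept].to_numpy(dtype=float)
    chip = chip_values.loc[genes, kept].to_numpy(dtype=float)
    rows = []
    for i, g in enumerate(genes):
        ok = ~(np.isnan(rna[i]) | np.isnan(chip[i]))
        n = int(ok.sum())
        if n < MIN_PAIRS:
            rho = float("nan")
        else:
            rho = spearman_rho(rna[i, ok], chip[i, ok])
        rows.append((g, antibody, rho, n, classify_correlation(rho)))
    return pd.DataFrame(rows, columns=["gene_id", "antibody", "rho",
                                       "n_pairs", "class"]).set_index("gene_id")


def classify_correlation(rho: float) -> str | None:
    """high (rho > 0.2), low (rho < -0.2), else middle; NaN unclassified."""
    if rho is None or np.isnan(rho):
        return None
    if rho > HIGH_THRESHOLD:
        return "high"
    if rho < LOW_THRESHOLD:
        return "low"
    return "middle"


def correlation_groups(polii_class: pd.Series, k4_class: pd.Series) -> pd.Series:
    """Five-way grouping from the Pol II and H3K4me3 classes.

    Precedence: both high; Pol II-only high; H3K4me3-only high; both
    low; everything else middle.  Genes missing either class are
    ungrouped (NaN).
    """
    idx = polii_class.index.union(k4_class.index)
    p = polii_class.reindex(idx)
    k = k4_class.reindex(idx)
    out = pd.Series(np.nan, index=idx, dtype=object)
    both = p.notna() & k.notna()
    out[both & (p == "high") & (k == "high")] = "both_high"
    out[both & (p == "high") & (k != "high")] = "polII_only_high"
    out[both & (p != "high") & (k == "high")] = "K4_only_high"
    out[both & (p == "low") & (k == "low")] = "both_low"
    out[both & out.isna()] = "middle"
    return out


def phase_signal_comparison(gene_values: pd.Series, phase_labels: pd.Series,
                            reference_phase: str = "S",
                            family_size: int | None = None) -> pd.DataFrame:
    """Each phase group's values against the reference (S) phase.

    Welch t per phase vs the reference, Bonferroni-adjusted over the
    number of phase-vs-reference comparisons in the family, plus a
    one-way ANOVA row across all phase groups.  Genes should already be
    filtered for inclusion (e.g. positive ChIP signal at >= 2 time
    points).  Phases with < 2 genes are marked not computable.
    """
    v = gene_values.dropna()
    lab = phase_labels.reindex(v.index).dropna()
    v = v.loc[lab.index]
    ref = v[lab == reference_phase]
    others = [p for p in lab.unique() if p != reference_phase]
    m = family_size if family_size is not None else len(others)
    rows = []
    for p in others:
        grp = v[lab == p]
        if len(grp) < 2 or len(ref) < 2:
            rows.append({"phase": p, "n": len(grp), "statistic": np.nan,
                         "df": np.nan, "p": np.nan, "p_adj": np.nan,
                         "method": "welch_t"})
            continue
        r = welch_t(grp, ref)
        rows.append({"phase": p, "n": len(grp), "statistic": r.statistic,
                     "df": r.df, "p": r.pvalue,
                     "p_adj": float(bonferroni([r.pvalue], m)[0]),
                     "method": "welch_t"})
    groups = [v[lab == p] for p in lab.unique() if (lab == p).sum() >= 2]
    if len(groups) >= 2:
        a = one_way_anova(groups)
        rows.append({"phase": "ALL", "n": int(sum(len(g) for g in groups)),
                     "statistic": a.statistic, "df": a.df, "p": a.pvalue,
                     "p_adj": np.nan, "method": "one_way_anova"})
    return pd.DataFrame(rows)


def compare_correlation_sets(rho: pd.Series, gene_sets: dict[str, list[str]],
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set-level correlation comparison (e.g. CC vs !CC_high vs !CC_low).

    Returns (per-set table, pairwise table).  Per set: n, mean rho, and
    a one-sample t against 0.  Pairwise: two-tailed Welch t between
    every pair of sets.  Empty sets are skipped with a warning.
    """
    values = {}
    for name, genes in gene_sets.items():
        x = rho.reindex([g for g in genes if g in rho.index]).dropna()
        if x.empty:
            warnings.warn(f"gene set {name!r} has no correlation values; skipped")
            continue
        values[name] = x
    per_set = []
    for name, x in values.items():
        r = one_sample_t(x, 0.0)
        per_set.append({"set": name, "n": len(x), "mean_rho": float(x.mean()),
                        "t": r.statistic, "df": r.df, "p": r.pvalue})
    names = list(values)
    pairwise = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = welch_t(values[a], values[b])
            pairwise.append({"set_a": a, "set_b": b, "t": r.statistic,
                             "df": r.df, "p": r.pvalue})
    return pd.DataFrame(per_set), pd.DataFrame(pairwise)


def cumulative_distribution(rho: pd.Series, genes) -> pd.DataFrame:
    """Empirical CDF of a gene set's correlations (for Fig-3A/B style plots)."""
    x = np.sort(rho.reindex([g for g in genes if g in rho.index]).dropna())
    return pd.DataFrame({"rho": x, "cumfrac": np.arange(1, x.size + 1) / x.size})


def select_lncrna_candidates(cyclic_genes, biotypes: pd.Series,
                             polii: pd.DataFrame, k4: pd.DataFrame,
                             phase_assignments: pd.DataFrame | None = None,
                             ) -> pd.DataFrame:
    """Ranked table of cyclic lncRNAs by RNA-ChIP correlation.

    Candidates are cyclic genes annotated lncRNA.  ``highly_correlated``
    flags a high class for Pol II or H3K4me3.  Rank score is
    max(rho_PolII, rho_K4), with both-high genes ranked ahead of the
    rest.
    """
    lnc = [g for g in cyclic_genes if biotypes.get(g) == "lncRNA"]
    rows = []
    for g in lnc:
        rp = polii["rho"].get(g, np.nan)
        rk = k4["rho"].get(g, np.nan)
        cp = polii["class"].get(g)
        ck = k4["class"].get(g)
        group = correlation_groups(pd.Series({g: cp}), pd.Series({g: ck})).iloc[0]
        rows.append({
            "gene_id": g,
            "rho_polII": rp, "rho_H3K4me3": rk,
            "class_polII": cp, "class_H3K4me3": ck,
            "group": group,
            "highly_correlated": (cp == "high") or (ck == "high"),
            "both_high": (cp == "high") and (ck == "high"),
            "rank_score": np.nanmax([rp, rk]) if not (
                pd.isna(rp) and pd.isna(rk)) else np.nan,
            "phase": (phase_assignments["phase"].get(g)
                      if phase_assignments is not None else None),
        })
    out = pd.DataFrame(rows, columns=[
        "gene_id", "rho_polII", "rho_H3K4me3", "class_polII", "class_H3K4me3",
        "group", "highly_correlated", "both_high", "rank_score", "phase"])
    if out.empty:
        return out.set_index("gene_id")
    return out.sort_values(["both_high", "rank_score"],
                           ascending=[False, False]).set_index("gene_id")
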