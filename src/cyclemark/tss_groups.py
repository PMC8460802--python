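"""TSS-arrangement grouping and enrichment for highly correlated genes.

Genes are grouped by whether they have a single distinct TSS or
multiple TSSs all within 1 kb, and by whether any other gene has a TSS
within 10 kb of the representative TSS:

    group 1: single TSS, neighbor within 10 kb
    group 2: single TSS, isolated
    group 3: multiple TSSs (<= 1 kb span), neighbor within 10 kb
    group 4: multiple TSSs (<= 1 kb span), isolated
    ungrouped: TSS span > 1 kb (PCNA-like far-spaced variants)

Fisher's exact test then asks whether each group is enriched for genes
whose RNA profile is highly correlated with the ChIP signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .annotation import neighbor_distances
from .stats import fisher_exact_2x2

NEIGHBOR_WINDOW = 10_000
MULTI_SPAN = 1_000


def classify_tss_groups(tss_catalog: pd.DataFrame,
                        neighbor_window: int = NEIGHBOR_WINDOW,
                        multi_span: int = MULTI_SPAN) -> pd.DataFrame:
    """Group assignment per gene from the TSS catalog.

    Distinct TSSs are exact-coordinate-identical transcript 5' ends
    collapsed; the neighbor search uses each gene's representative TSS
    against all transcript TSSs of other genes.
    """
    dist = neighbor_distances(tss_catalog)
    span = tss_catalog["tss_span"]
    multi = tss_catalog["n_distinct_tss"] >= 2
    near = dist <= neighbor_window
    group = pd.Series("ungrouped", index=tss_catalog.index, dtype=object)
    single = ~multi
    ok = span <= multi_span
    group[ok & single & near] = "1"
    group[ok & single & ~near] = "2"
    group[ok & multi & near] = "3"
    group[ok & multi & ~near] = "4"
    return pd.DataFrame({"group": group, "tss_span": span,
                         "neighbor_distance": dist})


def fisher_enrichment(groups: pd.Series, high_flags: pd.Series,
                      background) -> pd.DataFrame:
    """Enrichment of highly correlated genes per TSS group.

    For each group the 2x2 table is (in group vs rest of background) x
    (high vs not high); the odds ratio is the cross-product ratio
    (Haldane 0.5 correction when a cell is zero) and p is the two-sided
    Fisher exact probability.  Empty groups are skipped.
    """
    bg = [g for g in background if g in groups.index and g in high_flags.index]
    grp = groups.reindex(bg)
    high = high_flags.reindex(bg).astype(bool)
    rows = []
    for label in ("1", "2", "3", "4"):
        in_g = grp == label
        if not in_g.any():
            continue
        a = int((in_g & high).sum())
        b = int((in_g & ~high).sum())
        c = int((~in_g & high).sum())
        d = int((~in_g & ~high).sum())
        orr, p = fisher_exact_2x2([[a, b], [c, d]])
        rows.append({"group": label, "n": int(in_g.sum()), "n_high": a,
                     "odds_ratio": orr, "p": p})
    return pd.DataFrame(rows)
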