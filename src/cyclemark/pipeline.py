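"""End-to-end composition of the pipeline stages.

Convenience functions wiring the module-level operations together for
the common case: a complete simulated (or equivalently structured
real) dataset in, cyclic calls / ChIP signal tracks / RNA-ChIP
correlation tables out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import select_tss
from .chip import TssSignalTrack, call_promoter_marks, quantify_chip
from .design import TimeCourseDesign, sample_id
from .expression import WeightedLogExpression, filter_zero_count, mean_profile, voom_transform
from .integrate import correlate_rna_chip
from .phases import assign_phases, build_marker_profiles, markers_from_truth
from .pls import PlsResult, gene_significance
from .synthetic import SimulatedDataset


def facs_as_response(fractions: pd.DataFrame) -> pd.DataFrame:
    """FACS fraction matrix re-indexed by sample id, ready as PLS Y."""
    out = fractions.copy()
    out.index = [sample_id(r, t) for r, t in fractions.index]
    return out


def detect_cyclic_genes(counts: pd.DataFrame, fractions: pd.DataFrame,
                        design: TimeCourseDesign, n_perm: int = 999,
                        seed: int = 0, q_threshold: float = 0.05,
                        ) -> tuple[WeightedLogExpression, PlsResult]:
    """Filter, transform, and run the permutation PLS detection."""
    filtered = filter_zero_count(counts)
    expr = voom_transform(filtered)
    X = expr.values.T
    Y = facs_as_response(fractions).loc[X.index]
    res = gene_significance(X, Y, design, n_perm=n_perm, seed=seed,
                            q_threshold=q_threshold, weights=expr.weights)
    return expr, res


def quantify_all_chip(dataset: SimulatedDataset,
                      antibodies: tuple[str, ...] = ("polII", "H3K4me3", "H3K27me3"),
                      keep_bins: bool = False) -> dict[str, TssSignalTrack]:
    """TSS signal tracks for every antibody in a simulated dataset."""
    catalog = select_tss(dataset.annotation)
    inputs = {s: df for (ab, s), df in dataset.reads.items() if ab == "input"}
    tracks = {}
    for ab in antibodies:
        reads = {s: df for (a, s), df in dataset.reads.items() if a == ab}
        if not reads:
            continue
        tracks[ab] = quantify_chip(reads, inputs, catalog, dataset.chrom_sizes,
                                   antibody=ab, keep_bins=keep_bins)
    return tracks


def assign_cyclic_phases(expr: WeightedLogExpression, cyclic_genes,
                         truth: pd.DataFrame, design: TimeCourseDesign,
                         ) -> pd.DataFrame:
    """Phase assignment for cyclic genes using truth-designated markers."""
    profiles = mean_profile(expr.values, design)
    markers = markers_from_truth(truth)
    phase_profiles = build_marker_profiles(profiles, markers)
    genes = [g for g in cyclic_genes if g in profiles.index]
    return assign_phases(profiles, genes, phase_profiles)


@dataclass
class ChipCorrelations:
    """Per-antibody RNA-ChIP correlation tables plus promoter marks."""

    correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    marks: pd.DataFrame | None = None


def correlate_all(expr: WeightedLogExpression,
                  tracks: dict[str, TssSignalTrack],
                  design: TimeCourseDesign,
                  min_positive: int = 2) -> ChipCorrelations:
    """Spearman RNA-vs-ChIP tables for every antibody, plus mark calls."""
    out = ChipCorrelations()
    for ab, track in tracks.items():
        out.correlations[ab] = correlate_rna_chip(
            expr.values, track.signals, design, antibody=ab)
    if tracks:
        out.marks = call_promoter_marks(tracks, design, min_positive=min_positive)
    return out
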