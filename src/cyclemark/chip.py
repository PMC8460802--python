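"""TSS-window ChIP-seq quantification from aligned read positions.

Reads (BED intervals, 0-based half-open) are extended from their 5' end
in the strand direction to the fragment length (read length 75 +
extension 75 = 150 bp).  The 10,000 bp window around each gene's
representative TSS is split into 200 bins of 50 bp; each read is
assigned to exactly one bin — the bin containing its extended-fragment
midpoint.  Bin counts are RPKM-scaled, divided by the mean input
coverage of the same window (log2 ratio with a pseudo-count), and the
per-gene scalar signal is the oriented bin containing the point
TSS + 75.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import TimeCourseDesign
from .expression import mean_profile

WINDOW = 10_000
BIN_SIZE = 50
N_BINS = WINDOW // BIN_SIZE            # 200
TSS_POINT_OFFSET = 75
#: oriented bin holding TSS + 75: floor((5000 + 75) / 50)
TSS_BIN = (WINDOW // 2 + TSS_POINT_OFFSET) // BIN_SIZE


def extend_reads(reads: pd.DataFrame, chrom_sizes: dict[str, int],
                 extension: int = 75, read_length: int = 75,
                 ) -> tuple[pd.DataFrame, int]:
    """Extend each read from its 5' end to read_length + extension bp.

    Intervals are clipped at chromosome bounds; the number of clipped
    reads is returned alongside.
    """
    frag = read_length + extension
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    minus = reads["strand"].to_numpy() == "-"
    fstart = np.where(minus, end - frag, start)
    fend = np.where(minus, end, start + frag)
    sizes = reads["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    clipped = int(((fstart < 0) | (fend > sizes)).sum())
    if clipped:
        warnings.warn(f"{clipped} extended reads clipped at chromosome ends")
    fstart = np.clip(fstart, 0, sizes)
    fend = np.clip(fend, 0, sizes)
    out = pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "start": fstart,
                        "end": fend, "strand": reads["strand"].to_numpy()})
    return out, clipped


def compute_coverage(reads: pd.DataFrame, chrom_sizes: dict[str, int],
                     extension: int = 75, read_length: int = 75,
                     ) -> tuple[dict[str, np.ndarray], float]:
    """Per-base pileup of extended reads plus the RPKM scale factor.

    RPKM of any interval = count * 1e9 / (interval_length * total_reads);
    the returned factor is ``1e9 / total_reads`` so that
    ``coverage_sum * factor / length`` is the interval's RPKM.
    Intended for modest genomes (dense per-base arrays).
    """
    frags, _ = extend_reads(reads, chrom_sizes, extension, read_length)
    cov = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    for c, sub in frags.groupby("chrom"):
        delta = np.zeros(chrom_sizes[c] + 1, dtype=np.int64)
        np.add.at(delta, sub["start"].to_numpy(), 1)
        np.add.at(delta, sub["end"].to_numpy(), -1)
        cov[c] = np.cumsum(delta[:-1])
    total = len(reads)
    factor = 1e9 / total if total else 0.0
    return cov, factor


def fragment_midpoints(reads: pd.DataFrame, chrom_sizes: dict[str, int],
                       extension: int = 75, read_length: int = 75,
                       ) -> pd.DataFrame:
    """Count point of every read: 5' end + half the fragment, strand-aware.

    For the default 150 bp fragment this is the fragment midpoint.  It
    is defined from the 5' end in the strand direction (not as the
    arithmetic interval center) so that mirroring the genome and all
    strands maps count points exactly onto their reflections — an
    even-length interval has no strand-neutral central base.
    """
    half = (read_length + extension) // 2
    start = reads["start"].to_numpy(dtype=np.int64)
    end = reads["end"].to_numpy(dtype=np.int64)
    minus = reads["strand"].to_numpy() == "-"
    pos = np.where(minus, end - 1 - half, start + half)
    sizes = reads["chrom"].map(chrom_sizes).to_numpy(dtype=np.int64)
    pos = np.clip(pos, 0, sizes - 1)
    return pd.DataFrame({"chrom": reads["chrom"].to_numpy(), "pos": pos})


def bin_tss_region(reads: pd.DataFrame, tss_catalog: pd.DataFrame,
                   chrom_sizes: dict[str, int], extension: int = 75,
                   read_length: int = 75) -> pd.DataFrame:
    """200-bin read counts around each gene's representative TSS.

    The window is [TSS - 5000, TSS + 5000) in genome coordinates; bin i
    covers [TSS - 5000 + 50 i, TSS - 5000 + 50 (i + 1)).  A read falls
    in the single bin containing its extended-fragment count point.  For
    minus-strand genes the window is anchored one base 3'-ward (so the
    two strand frames are exact mirror images) and the bin order is
    reversed so the index increases downstream.  Windows running off a
    chromosome keep their (empty) partial bins.

    Returns genes x 200 integer counts.
    """
    mids = fragment_midpoints(reads, chrom_sizes, extension, read_length)
    by_chrom = {c: np.sort(sub["pos"].to_numpy()) for c, sub in mids.groupby("chrom")}
    half = WINDOW // 2
    counts = np.zeros((len(tss_catalog), N_BINS), dtype=np.int64)
    for i, (gid, row) in enumerate(tss_catalog.iterrows()):
        pos = by_chrom.get(row["chrom"])
        if pos is None:
            continue
        anchor = row["tss"] + (1 if row["strand"] == "-" else 0)
        edges = anchor - half + BIN_SIZE * np.arange(N_BINS + 1)
        binned = np.diff(np.searchsorted(pos, edges))
        if row["strand"] == "-":
            binned = binned[::-1]
        counts[i] = binned
    return pd.DataFrame(counts, index=tss_catalog.index)


def bins_to_rpkm(bin_counts: pd.DataFrame, total_reads: int) -> pd.DataFrame:
    """RPKM per 50 bp bin given the library's total read count."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    return bin_counts * (1e9 / (BIN_SIZE * total_reads))


def normalize_to_input(chip_bins_rpkm: pd.DataFrame,
                       input_bins_rpkm_mean: pd.DataFrame,
                       pseudocount: float = 0.5) -> pd.DataFrame:
    """log2 ratio of ChIP to mean input RPKM, bin by bin.

    ``input_bins_rpkm_mean`` is the element-wise mean RPKM over the
    input samples for the same gene windows.  The pseudo-count bounds
    the ratio and makes an all-zero bin normalize to exactly 0.
    """
    if not chip_bins_rpkm.index.equals(input_bins_rpkm_mean.index):
        raise ValueError("ChIP and input bins must cover the same genes")
    return np.log2((chip_bins_rpkm + pseudocount)
                   / (input_bins_rpkm_mean + pseudocount))


def tss_signal(normalized_bins: pd.DataFrame) -> pd.Series:
    """Scalar per-gene signal: the oriented bin containing TSS + 75."""
    return normalized_bins.iloc[:, TSS_BIN].rename("tss_signal")


@dataclass
class TssSignalTrack:
    """Per-antibody scalar TSS signals (genes x samples) and the
    underlying normalized bin matrices per sample."""

    antibody: str
    signals: pd.DataFrame                                  # genes x samples
    bins: dict[str, pd.DataFrame] = field(default_factory=dict)


def quantify_chip(reads_by_sample: dict[str, pd.DataFrame],
                  input_by_sample: dict[str, pd.DataFrame],
                  tss_catalog: pd.DataFrame, chrom_sizes: dict[str, int],
                  antibody: str = "", pseudocount: float = 0.5,
                  keep_bins: bool = False) -> TssSignalTrack:
    """Full quantification for one antibody across samples.

    The input normalizer is the across-input-sample mean RPKM of each
    window bin (window-local, not genome-wide).
    """
    if not input_by_sample:
        raise ValueError("missing input track")
    input_mean = None
    for s, reads in input_by_sample.items():
        rb = bins_to_rpkm(bin_tss_region(reads, tss_catalog, chrom_sizes),
                          total_reads=len(reads))
        input_mean = rb if input_mean is None else input_mean + rb
    input_mean = input_mean / len(input_by_sample)

    signals = {}
    bins: dict[str, pd.DataFrame] = {}
    for s, reads in reads_by_sample.items():
        rb = bins_to_rpkm(bin_tss_region(reads, tss_catalog, chrom_sizes),
                          total_reads=len(reads))
        norm = normalize_to_input(rb, input_mean, pseudocount=pseudocount)
        signals[s] = tss_signal(norm)
        if keep_bins:
            bins[s] = norm
    return TssSignalTrack(antibody=antibody,
                          signals=pd.DataFrame(signals), bins=bins)


def positive_timepoint_counts(signals: pd.DataFrame, design: TimeCourseDesign,
                              assay: str | None = None) -> pd.Series:
    """Number of time points with positive mean signal, per gene."""
    prof = mean_profile(signals, design, assay)
    return (prof > 0).sum(axis=1)


def call_promoter_marks(tracks: dict[str, TssSignalTrack],
                        design: TimeCourseDesign,
                        min_positive: int = 2) -> pd.DataFrame:
    """Presence flags per antibody and their combinations.

    A mark is present at a promoter iff the normalized TSS signal is
    positive at >= ``min_positive`` time points (per-time-point mean
    over replicates, respecting each assay's exclusions).  Combination
    columns (e.g. bivalent H3K4me3/H3K27me3) are logical ANDs.
    """
    flags = {}
    for ab, track in tracks.items():
        flags[ab] = positive_timepoint_counts(
            track.signals, design, assay=ab) >= min_positive
    out = pd.DataFrame(flags)
    abs_ = list(tracks)
    for i, a in enumerate(abs_):
        for b in abs_[i + 1:]:
            out[f"{a}+{b}"] = out[a] & out[b]
    return out


def mark_summary(marks: pd.DataFrame, gene_set) -> pd.Series:
    """Percentage of genes in ``gene_set`` carrying each mark/combination."""
    sub = marks.loc[[g for g in gene_set if g in marks.index]]
    if sub.empty:
        raise ValueError("no genes from the set have ChIP signals")
    return 100.0 * sub.mean(axis=0)
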