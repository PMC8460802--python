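"""Gene/transcript annotation, GTF I/O, and representative-TSS selection.

Coordinates are 0-based half-open internally (BED convention); the GTF
reader/writer converts (GTF is 1-based inclusive).  Only ``gene`` and
``transcript`` features are modeled — that is all the TSS-window
quantification needs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype"]
TX_COLUMNS = ["transcript_id", "gene_id", "chrom", "start", "end", "strand"]


@dataclass
class GeneAnnotation:
    """Genes and their transcripts as two aligned DataFrames."""

    genes: pd.DataFrame
    transcripts: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes[GENE_COLUMNS].reset_index(drop=True)
        self.transcripts = self.transcripts[TX_COLUMNS].reset_index(drop=True)
        for df in (self.genes, self.transcripts):
            if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
                raise ValueError("invalid coordinates (need 0 <= start < end)")
        orphans = set(self.transcripts["gene_id"]) - set(self.genes["gene_id"])
        if orphans:
            raise ValueError(f"transcripts reference unknown genes: {sorted(orphans)[:5]}")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneAnnotation):
            return NotImplemented
        return self.genes.equals(other.genes) and self.transcripts.equals(other.transcripts)


def tss_of(start: int, end: int, strand: str) -> int:
    """Strand-aware 5' end of a half-open interval."""
    return int(start) if strand == "+" else int(end) - 1


def write_gtf(annotation: GeneAnnotation, path) -> None:
    with open(path, "w") as fh:
        for _, g in annotation.genes.iterrows():
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(f"{g.chrom}\tcyclemark\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            txs = annotation.transcripts[annotation.transcripts["gene_id"] == g.gene_id]
            for _, t in txs.iterrows():
                attrs = (f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                         f'gene_biotype "{g.biotype}";')
                fh.write(f"{t.chrom}\tcyclemark\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                         f"{t.strand}\t.\t{attrs}\n")


def read_gtf(path) -> GeneAnnotation:
    """Parse gene/transcript features from a GTF file (other features ignored)."""
    genes, txs = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _src, feature, start, end, _sc, strand, _fr, attr_str = fields[:9]
            attrs = dict(_ATTR_RE.findall(attr_str))
            start0, end0 = int(start) - 1, int(end)
            if feature == "gene":
                genes.append((attrs["gene_id"], chrom, start0, end0, strand,
                              attrs.get("gene_biotype", "protein_coding")))
            elif feature == "transcript":
                txs.append((attrs["transcript_id"], attrs["gene_id"], chrom,
                            start0, end0, strand))
    return GeneAnnotation(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        transcripts=pd.DataFrame(txs, columns=TX_COLUMNS),
    )


def select_tss(annotation: GeneAnnotation) -> pd.DataFrame:
    """Representative TSS per gene: the longest transcript variant's 5' end.

    Ties on genomic span are broken by lower start coordinate, then by
    lexicographic transcript id.  The catalog also records every
    distinct transcript TSS and the maximum pairwise distance between
    them (``tss_span``) — genes whose variants start far apart (like
    PCNA's two TSSs 6,664 bp apart) keep the longest variant even when
    a shorter one carries the expression.

    Returns a DataFrame indexed by gene_id with columns chrom, tss,
    strand, transcript_id, all_tss (tuple), n_distinct_tss, tss_span.
    """
    tx = annotation.transcripts
    if tx.empty:
        raise ValueError("annotation has no transcripts")
    missing = set(annotation.genes["gene_id"]) - set(tx["gene_id"])
    if missing:
        raise ValueError(f"genes without transcripts: {sorted(missing)[:5]}")
    rows = []
    for gene_id, sub in tx.groupby("gene_id", sort=False):
        span = sub["end"] - sub["start"]
        order = sub.assign(span=span).sort_values(
            by=["span", "start", "transcript_id"],
            ascending=[False, True, True], kind="mergesort")
        best = order.iloc[0]
        all_tss = sorted({tss_of(s, e, st)
                          for s, e, st in zip(sub["start"], sub["end"], sub["strand"])})
        rows.append({
            "gene_id": gene_id,
            "chrom": best["chrom"],
            "tss": tss_of(best["start"], best["end"], best["strand"]),
            "strand": best["strand"],
            "transcript_id": best["transcript_id"],
            "all_tss": tuple(all_tss),
            "n_distinct_tss": len(all_tss),
            "tss_span": int(all_tss[-1] - all_tss[0]),
        })
    cat = pd.DataFrame(rows).set_index("gene_id")
    # keep gene order of the annotation
    return cat.loc[[g for g in annotation.genes["gene_id"] if g in cat.index]]


def neighbor_distances(tss_catalog: pd.DataFrame) -> pd.Series:
    """Distance from each gene's representative TSS to the nearest TSS
    of any *other* gene (any of its transcript TSSs), per chromosome.

    Genes alone on their chromosome get +inf.
    """
    out = pd.Series(np.inf, index=tss_catalog.index, dtype=float)
    for chrom, sub in tss_catalog.groupby("chrom"):
        # all transcript TSSs on this chromosome, labeled by owner gene
        owners, positions = [], []
        for gid, row in sub.iterrows():
            for t in row["all_tss"]:
                owners.append(gid)
                positions.append(t)
        owners = np.array(owners, dtype=object)
        positions = np.array(positions, dtype=float)
        for gid, row in sub.iterrows():
            foreign = positions[owners != gid]
            if foreign.size:
                out.loc[gid] = float(np.min(np.abs(foreign - row["tss"])))
    return out
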