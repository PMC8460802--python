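"""Synchronized cell-population simulator.

Emulates a double-thymidine-block release experiment: cells start at
the G1/S boundary, move around the cycle at constant speed, and the
population's spread of cycle positions grows with time (synchrony
decay).  A cell's position is modeled as a wrapped normal on [0, 1);
the per-phase FACS fractions are the wrapped-normal mass over each
phase arc, the population expression of a cyclic gene is the cosine
profile of a single cell averaged over the position distribution, and
ChIP read intensity at a gene's TSS is tied (for coupled genes) to the
same latent expression.  Everything downstream of the simulator —
counts, reads, annotation, FACS table — is emitted in the standard
text formats the pipeline consumes, with a ground-truth table for
recovery tests.

Default calibration: a 14 h cycle with arcs G1 = 0.40, S = 0.35,
G2M = 0.25 of the cycle, initial position spread 0.09 and dispersion
growth 0.009 cycle-fractions per hour puts ~90% of cells in the first
S-phase wave and ~70% in the second, the synchrony decay the pipeline
is designed around.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .annotation import GENE_COLUMNS, TX_COLUMNS, GeneAnnotation, select_tss
from .design import TimeCourseDesign, sample_id

PHASES_3 = ("G1", "S", "G2M")

#: default cycle arcs: G1 [0, 0.40), S [0.40, 0.75), G2M [0.75, 1.0)
DEFAULT_PHASE_INTERVALS = {"G1": (0.0, 0.40), "S": (0.40, 0.75), "G2M": (0.75, 1.0)}


@dataclass(frozen=True)
class SynchronyModel:
    """Wrapped-normal model of a synchronized population's cycle position."""

    cycle_length_hours: float = 14.0
    release_position: float = 0.40  # the G1->S boundary of the default arcs
    sigma0: float = 0.09            # initial position spread (cycle fractions)
    kappa: float = 0.009            # dispersion growth per hour
    phase_intervals: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_INTERVALS))
    replicate_jitter: float = 0.005  # per-sample jitter of the mean position

    def __post_init__(self) -> None:
        if self.cycle_length_hours <= 0:
            raise ValueError("cycle_length_hours must be positive")
        if self.sigma0 < 0 or self.kappa < 0:
            raise ValueError("dispersion parameters must be nonnegative")
        if not 0 <= self.release_position < 1:
            raise ValueError("release_position must lie in [0, 1)")
        arcs = sorted(self.phase_intervals.values())
        if arcs[0][0] != 0.0 or arcs[-1][1] != 1.0 or any(
                a[1] != b[0] for a, b in zip(arcs, arcs[1:])):
            raise ValueError("phase arcs must be disjoint and cover [0, 1)")

    def position_at(self, hours: float) -> tuple[float, float]:
        """(mean, sd) of the wrapped-normal position at time ``hours``."""
        mu = (self.release_position + hours / self.cycle_length_hours) % 1.0
        sd = float(np.hypot(self.sigma0, self.kappa * hours))
        return mu, sd


def wrapped_normal_arc_mass(mu: float, sd: float, a: float, b: float,
                            n_images: int = 7) -> float:
    """Mass of a wrapped N(mu, sd) on the arc [a, b) of [0, 1).

    Computed by a truncated image sum over at least ``n_images`` copies
    of the line; for sd = 0 the mass degenerates to an indicator of the
    arc containing mu mod 1.
    """
    if not (0 <= a < b <= 1):
        raise ValueError("arc must satisfy 0 <= a < b <= 1")
    mu = mu % 1.0
    if sd < 1e-12:
        return 1.0 if a <= mu < b else 0.0
    k = max(n_images, int(np.ceil(4 * sd)) + n_images)
    ks = np.arange(-k, k + 1)
    return float(np.sum(norm.cdf((b + ks - mu) / sd) - norm.cdf((a + ks - mu) / sd)))


def simulate_synchrony(model: SynchronyModel, design: TimeCourseDesign,
                       seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """FACS phase-fraction matrix and per-sample position distributions.

    Returns ``(fractions, positions)`` where ``fractions`` is indexed by
    (replicate, hours) with columns G1/S/G2M summing to 1, and
    ``positions[(replicate, hours)] = (mean, sd)`` of the wrapped-normal
    position.  Replicates differ only by a small seeded jitter of the
    mean position, so rows still sum to 1 exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    phases = list(model.phase_intervals)
    rows, positions = [], {}
    for rep in design.replicates:
        for t in design.time_points_hours:
            mu, sd = model.position_at(t)
            mu = (mu + rng.normal(0.0, model.replicate_jitter)) % 1.0
            positions[(rep, t)] = (mu, sd)
            rows.append([wrapped_normal_arc_mass(mu, sd, a, b)
                         for a, b in (model.phase_intervals[p] for p in phases)])
    idx = pd.MultiIndex.from_tuples(
        [(r, t) for r in design.replicates for t in design.time_points_hours],
        names=["replicate", "hours"])
    fractions = pd.DataFrame(rows, index=idx, columns=phases)
    # renormalize away the (tiny) image-sum truncation error
    fractions = fractions.div(fractions.sum(axis=1), axis=0)
    return fractions, positions


# ---------------------------------------------------------------------------
# ground truth

TRUTH_COLUMNS = [
    "gene_id", "biotype", "cyclic", "peak_phase", "amplitude", "baseline",
    "dispersion", "slope_polII", "slope_H3K4me3", "slope_H3K27me3",
    "n_tss", "tss_spacing", "has_neighbor", "neighbor_distance",
]


def make_truth(n_genes: int = 1000, cyclic_frac: float = 0.10,
               lncrna_frac: float = 0.10, dispersion: float = 0.05,
               amplitude_range: tuple[float, float] = (1.0, 2.0),
               coupling_slope: float = 0.8, seed: int = 0) -> pd.DataFrame:
    """Per-gene ground-truth table driving the whole simulation.

    Cyclic genes get a peak phase uniform on the cycle and a log2
    amplitude in ``amplitude_range``; they are ChIP-coupled for Pol II
    and H3K4me3 (positive slope) and weakly anti-coupled for H3K27me3.
    Non-cyclic genes are flat and uncoupled.  Baseline log2-CPM values
    are bimodal for non-cyclic genes (low ~N(3, 0.6), high ~N(7, 0.6))
    so the non-cyclic reference split has something to find.

    TSS layouts are assigned so that genes wanting a close neighbor come
    in consecutive pairs sharing the same requested TSS-to-TSS distance.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))
    n_cyclic = int(round(n_genes * cyclic_frac))
    gene_ids = [f"g{i:05d}" for i in range(n_genes)]

    cyclic = np.zeros(n_genes, dtype=bool)
    cyclic[rng.choice(n_genes, size=n_cyclic, replace=False)] = True

    biotype = np.where(rng.random(n_genes) < lncrna_frac, "lncRNA", "protein_coding")

    peak_phase = np.where(cyclic, rng.random(n_genes), 0.0)
    amplitude = np.where(cyclic, rng.uniform(*amplitude_range, n_genes), 0.0)

    baseline = np.empty(n_genes)
    hi = rng.random(n_genes) < 0.6
    baseline[hi] = rng.normal(7.0, 0.6, hi.sum())
    baseline[~hi] = rng.normal(3.0, 0.6, (~hi).sum())
    baseline[cyclic] = rng.normal(6.0, 0.8, n_cyclic)
    baseline = np.clip(baseline, 1.5, None)

    slope_pol = np.where(cyclic, coupling_slope, 0.0)
    slope_k4 = np.where(cyclic, coupling_slope, 0.0)
    slope_k27 = np.where(cyclic, -0.3 * coupling_slope, 0.0)

    # TSS layouts: ~15% single+neighbor, 20% single isolated,
    # ~20% multi(<1kb)+neighbor, 20% multi isolated, 10% far-spaced pair
    # (PCNA-like), remainder single isolated.
    n_tss = np.ones(n_genes, dtype=int)
    spacing = np.zeros(n_genes, dtype=int)
    has_neighbor = np.zeros(n_genes, dtype=bool)
    neighbor_distance = np.full(n_genes, np.nan)
    kinds = rng.choice(
        ["single_nb", "single_iso", "multi_nb", "multi_iso", "far"],
        size=n_genes, p=[0.15, 0.25, 0.20, 0.25, 0.15])
    for i, kind in enumerate(kinds):
        if kind in ("multi_nb", "multi_iso"):
            n_tss[i] = int(rng.integers(2, 4))
            spacing[i] = int(rng.integers(100, 501))
        elif kind == "far":
            n_tss[i] = 2
            spacing[i] = 6664
        if kind.endswith("_nb"):
            has_neighbor[i] = True
    # pair neighbor-wanting genes; an odd leftover becomes isolated
    nb_idx = np.flatnonzero(has_neighbor)
    if nb_idx.size % 2:
        has_neighbor[nb_idx[-1]] = False
        nb_idx = nb_idx[:-1]
    for a, b in nb_idx.reshape(-1, 2):
        d = float(rng.integers(3000, 9001))
        neighbor_distance[a] = neighbor_distance[b] = d

    return pd.DataFrame({
        "gene_id": gene_ids, "biotype": biotype, "cyclic": cyclic,
        "peak_phase": peak_phase, "amplitude": amplitude, "baseline": baseline,
        "dispersion": float(dispersion),
        "slope_polII": slope_pol, "slope_H3K4me3": slope_k4,
        "slope_H3K27me3": slope_k27,
        "n_tss": n_tss, "tss_spacing": spacing,
        "has_neighbor": has_neighbor, "neighbor_distance": neighbor_distance,
    })[TRUTH_COLUMNS]


# ---------------------------------------------------------------------------
# annotation generation

_GENE_BODY = 2000       # bp downstream of the last TSS
_ISOLATION_GAP = 25000  # bp between isolated placement runs


def generate_annotation(truth: pd.DataFrame, genome_length: int | None = None,
                        chrom: str = "chrSim", seed: int = 0,
                        ) -> tuple[GeneAnnotation, dict[str, int]]:
    """Lay the truth table's genes onto a synthetic chromosome.

    Each gene gets one transcript per TSS; all transcripts share the
    gene's 3' end, so the 5'-most TSS always belongs to the longest
    variant and is the representative TSS downstream.  Genes requesting
    a close neighbor were paired in the truth table; the pair is placed
    with exactly the requested representative-TSS-to-TSS distance.
    Everything else sits >= 25 kb from any foreign TSS.

    Returns the annotation and a ``{chrom: length}`` mapping.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    # placement order: neighbor pairs together, then singles
    order: list[tuple[int, ...]] = []
    seen = set()
    nb_idx = [i for i in truth.index[truth["has_neighbor"]]]
    for a, b in zip(nb_idx[0::2], nb_idx[1::2]):
        order.append((a, b))
        seen.update((a, b))
    order.extend((i,) for i in truth.index if i not in seen)

    genes, txs = [], []
    cursor = _ISOLATION_GAP

    def place(i: int, rep_tss: int) -> int:
        """Emit records for gene i with its representative TSS at rep_tss;
        return the rightmost coordinate used."""
        row = truth.loc[i]
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(row["n_tss"])
        sp = int(row["tss_spacing"])
        length = (k - 1) * sp + _GENE_BODY
        if strand == "+":
            start, end = rep_tss, rep_tss + length
            tss_list = [rep_tss + j * sp for j in range(k)]
            tx_iv = [(t, end) for t in tss_list]
        else:
            start, end = rep_tss + 1 - length, rep_tss + 1
            tss_list = [rep_tss - j * sp for j in range(k)]
            tx_iv = [(start, t + 1) for t in tss_list]
        if start < 0:
            raise ValueError("gene placed before the chromosome start")
        genes.append((row["gene_id"], chrom, start, end, strand, row["biotype"]))
        for j, (s, e) in enumerate(tx_iv):
            txs.append((f"{row['gene_id']}.t{j}", row["gene_id"], chrom, s, e, strand))
        return end

    for run in order:
        rep_tss = cursor + _GENE_BODY  # headroom for minus-strand bodies
        right = place(run[0], rep_tss)
        if len(run) == 2:
            d = int(truth.loc[run[0], "neighbor_distance"])
            right = max(right, place(run[1], rep_tss + d))
        cursor = right + _ISOLATION_GAP + 8000  # 8 kb guards the far-TSS layouts

    needed = cursor + _ISOLATION_GAP
    if genome_length is None:
        genome_length = needed
    elif genome_length < needed:
        raise ValueError(f"genome_length {genome_length} too small; need {needed}")
    ann = GeneAnnotation(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        transcripts=pd.DataFrame(txs, columns=TX_COLUMNS))
    return ann, {chrom: int(genome_length)}


# ---------------------------------------------------------------------------
# expression

_GRID = 512


def latent_expression(truth: pd.DataFrame, positions: dict,
                      design: TimeCourseDesign) -> pd.DataFrame:
    """Noise-free population log2 expression per gene x sample.

    A single cell at cycle position theta expresses gene g at
    ``baseline + amplitude * cos(2*pi*(theta - peak_phase))`` (log2
    scale); the population value is the expectation under the sample's
    wrapped-normal position distribution, evaluated on a 512-point
    grid.  Averaging over a wider distribution shrinks the cosine term,
    so amplitudes damp as synchrony decays.
    """
    theta = (np.arange(_GRID) + 0.5) / _GRID
    psi = truth["peak_phase"].to_numpy()
    amp = truth["amplitude"].to_numpy()
    base = truth["baseline"].to_numpy()
    cols, data = [], []
    for rep, t in design.cells:
        mu, sd = positions[(rep, t)]
        if sd == 0:
            w = np.zeros(_GRID)
            w[int(mu * _GRID) % _GRID] = 1.0
        else:
            k = max(7, int(np.ceil(4 * sd)) + 7)
            ks = np.arange(-k, k + 1)[:, None]
            w = norm.pdf((theta[None, :] + ks - mu) / sd).sum(axis=0)
            w /= w.sum()
        c1 = float(w @ np.cos(2 * np.pi * theta))
        s1 = float(w @ np.sin(2 * np.pi * theta))
        e_cos = c1 * np.cos(2 * np.pi * psi) + s1 * np.sin(2 * np.pi * psi)
        data.append(base + amp * e_cos)
        cols.append(sample_id(rep, t))
    return pd.DataFrame(np.column_stack(data), index=truth["gene_id"].to_numpy(),
                        columns=cols)


def simulate_expression(truth: pd.DataFrame, positions: dict,
                        design: TimeCourseDesign,
                        library_sizes: float | dict = 2e6,
                        seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix plus the noise-free latents.

    Counts for gene g in sample s are NB with mean
    ``library_size(s) * 2**latent / 1e6`` (the latent is on a log2-CPM
    scale) and the gene's overdispersion (var = m + phi * m^2).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    latents = latent_expression(truth, positions, design)
    if np.isscalar(library_sizes):
        lib = {s: float(library_sizes) for s in latents.columns}
    else:
        lib = {s: float(library_sizes[s]) for s in latents.columns}
    if any(v <= 0 for v in lib.values()):
        raise ValueError("library sizes must be positive")
    mean = np.power(2.0, latents.to_numpy()) * np.array(
        [lib[s] for s in latents.columns])[None, :] / 1e6
    phi = np.broadcast_to(truth["dispersion"].to_numpy()[:, None], mean.shape)
    counts = np.empty(mean.shape, dtype=np.int64)
    od = phi > 0  # NB with var = m + phi*m^2; phi = 0 degenerates to Poisson
    counts[od] = rng.negative_binomial(1.0 / phi[od], 1.0 / (1.0 + phi[od] * mean[od]))
    counts[~od] = rng.poisson(mean[~od])
    cm = pd.DataFrame(counts, index=latents.index, columns=latents.columns)
    return cm, latents


# ---------------------------------------------------------------------------
# ChIP reads

_KERNEL_HALF_WIDTH = 500  # triangular placement kernel around the TSS


def simulate_chip_reads(truth: pd.DataFrame, latents: pd.DataFrame,
                        annotation: GeneAnnotation, chrom_sizes: dict[str, int],
                        design: TimeCourseDesign,
                        antibodies: tuple[str, ...] = ("polII", "H3K4me3", "H3K27me3"),
                        reads_per_gene: float = 150.0,
                        input_depth: float | None = None,
                        fragment_length: int = 150, read_length: int = 75,
                        seed: int = 0) -> dict[tuple[str, str], pd.DataFrame]:
    """Per-(antibody, sample) read tables plus uniform-background input.

    For coupled genes the expected read count at a sample is affine in
    the latent expression: ``reads_per_gene * max(0.05, 1 + slope *
    (latent - baseline))``; uncoupled genes (slope 0) are flat.  Read
    counts are Poisson; extended-fragment midpoints follow a triangular
    kernel of half-width 500 bp around the representative TSS; strands
    are random.  Input tracks are uniform over the genome with expected
    depth ``input_depth`` (default: n_genes * reads_per_gene) per sample.

    Returns ``{(antibody_or_"input", sample_id): BED-like DataFrame}``
    with 0-based half-open read intervals of ``read_length`` bp, sorted
    by start.
    """
    if reads_per_gene <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    catalog = select_tss(annotation)
    tss = catalog.loc[truth["gene_id"], "tss"].to_numpy()
    chrom = catalog["chrom"].iloc[0]
    glen = chrom_sizes[chrom]
    if input_depth is None:
        input_depth = len(truth) * reads_per_gene
    half = fragment_length // 2
    out: dict[tuple[str, str], pd.DataFrame] = {}
    lat = latents.loc[truth["gene_id"].to_numpy()]
    base = truth["baseline"].to_numpy()
    for ab in antibodies:
        slope = truth[f"slope_{ab}"].to_numpy()
        for s in lat.columns:
            lam = reads_per_gene * np.maximum(
                0.05, 1.0 + slope * (lat[s].to_numpy() - base))
            n = rng.poisson(lam)
            total = int(n.sum())
            centers = np.repeat(tss, n).astype(float)
            centers += rng.triangular(-_KERNEL_HALF_WIDTH, 0, _KERNEL_HALF_WIDTH,
                                      size=total)
            centers = np.clip(np.rint(centers), half, glen - half).astype(np.int64)
            out[(ab, s)] = _reads_frame(chrom, centers, rng, half, read_length)
    for s in lat.columns:
        total = rng.poisson(input_depth)
        centers = rng.integers(half, glen - half, size=total)
        out[("input", s)] = _reads_frame(chrom, centers, rng, half, read_length)
    return out


def _reads_frame(chrom: str, centers: np.ndarray, rng, half: int,
                 read_length: int) -> pd.DataFrame:
    """Reads whose *extended-fragment* midpoint is at ``centers``."""
    minus = rng.random(centers.size) < 0.5
    start = np.where(minus, centers, centers - half)
    end = start + read_length
    df = pd.DataFrame({
        "chrom": chrom, "start": start.astype(np.int64),
        "end": end.astype(np.int64), "name": ".", "score": 0,
        "strand": np.where(minus, "-", "+"),
    })
    return df.sort_values(["start", "end"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# file emission

def write_bed(reads: pd.DataFrame, path) -> None:
    reads.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"])
    bad = df[(df["end"] <= df["start"]) | (df["start"] < 0)]
    if len(bad):
        raise ValueError(f"malformed BED interval at line {bad.index[0] + 1}")
    return df


def write_facs(fractions: pd.DataFrame, path) -> None:
    out = fractions.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_facs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df.set_index(["replicate", "hours"])


@dataclass
class SimulatedDataset:
    """Bundle of every pipeline input plus the generating truth."""

    design: TimeCourseDesign
    model: SynchronyModel
    truth: pd.DataFrame
    fractions: pd.DataFrame
    positions: dict
    annotation: GeneAnnotation
    chrom_sizes: dict[str, int]
    counts: pd.DataFrame
    latents: pd.DataFrame
    reads: dict[tuple[str, str], pd.DataFrame]


def simulate_dataset(n_genes: int = 1000, cyclic_frac: float = 0.10,
                     seed: int = 0, design: TimeCourseDesign | None = None,
                     model: SynchronyModel | None = None,
                     with_chip: bool = True,
                     antibodies: tuple[str, ...] = ("polII", "H3K4me3", "H3K27me3"),
                     reads_per_gene: float = 150.0,
                     **truth_kwargs) -> SimulatedDataset:
    """One-call simulation of a complete synchronized experiment."""
    design = design or TimeCourseDesign()
    model = model or SynchronyModel()
    truth = make_truth(n_genes=n_genes, cyclic_frac=cyclic_frac, seed=seed,
                       **truth_kwargs)
    fractions, positions = simulate_synchrony(model, design, seed=seed)
    annotation, chrom_sizes = generate_annotation(truth, seed=seed)
    counts, latents = simulate_expression(truth, positions, design, seed=seed)
    reads: dict[tuple[str, str], pd.DataFrame] = {}
    if with_chip:
        reads = simulate_chip_reads(truth, latents, annotation, chrom_sizes,
                                    design, antibodies=antibodies,
                                    reads_per_gene=reads_per_gene, seed=seed)
    return SimulatedDataset(design, model, truth, fractions, positions,
                            annotation, chrom_sizes, counts, latents, reads)
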