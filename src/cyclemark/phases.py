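"""Cell-cycle phase assignment by similarity to phase-marker profiles.

Each cyclic gene is assigned to one of five canonical phase labels
(G1/S, S, G2, G2/M, M/G1) by Pearson-correlating its z-scored
per-time-point mean profile with the average z-scored profiles of
known phase-marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PHASE_LABELS = ("G1/S", "S", "G2", "G2/M", "M/G1")

#: Cycle-fraction sub-arcs mapping the simulator's position circle onto
#: the five labels (release sits at the G1->S boundary, 0.40; arcs past
#: 1.0 wrap through 0).  Equal-width arcs centered on the canonical
#: positions — G1/S on the boundary itself, S mid-S, G2 and G2/M through
#: the G2M arc, M/G1 inside G1 — so that a correlation classifier whose
#: templates sit at arc centers has decision boundaries matching the
#: arc boundaries.  Used to turn a simulated gene's peak phase into a
#: truth label for recovery checks.
DEFAULT_PHASE_ARCS: dict[str, tuple[float, float]] = {
    "G1/S": (0.30, 0.50),
    "S": (0.50, 0.70),
    "G2": (0.70, 0.90),
    "G2/M": (0.90, 1.10),   # wraps: [0.90, 1) u [0, 0.10)
    "M/G1": (1.10, 1.30),   # wraps: [0.10, 0.30)
}


def truth_phase_label(peak_phase: float,
                      arcs: dict[str, tuple[float, float]] | None = None) -> str:
    """Five-label phase of a cycle position in [0, 1)."""
    arcs = arcs or DEFAULT_PHASE_ARCS
    psi = peak_phase % 1.0
    for label, (a, b) in arcs.items():
        if a <= psi < b or a <= psi + 1.0 < b:
            return label
    raise ValueError(f"phase arcs do not cover position {psi}")


def _zscore(profile: np.ndarray) -> np.ndarray:
    sd = profile.std(ddof=0)
    if sd == 0:
        return np.full_like(profile, np.nan)
    return (profile - profile.mean()) / sd


def build_marker_profiles(mean_profiles: pd.DataFrame,
                          markers: dict[str, list[str]]) -> pd.DataFrame:
    """Average z-scored marker profiles per phase.

    ``mean_profiles`` is genes x time points (as from
    :func:`cyclemark.expression.mean_profile`); ``markers`` maps each of
    the five phase labels to marker gene ids.  Markers absent from the
    matrix are ignored; a phase left without any detected marker raises.

    Returns phases x time points.
    """
    rows = {}
    for phase in PHASE_LABELS:
        present = [g for g in markers.get(phase, []) if g in mean_profiles.index]
        if not present:
            raise ValueError(f"no markers detected for phase {phase!r}")
        z = np.vstack([_zscore(mean_profiles.loc[g].to_numpy(dtype=float))
                       for g in present])
        rows[phase] = np.nanmean(z, axis=0)
    return pd.DataFrame(rows, index=mean_profiles.columns).T


@dataclass
class PhaseAssignment:
    gene_id: str
    phase: str | None                   # None when unassignable
    correlations: dict[str, float]


def assign_phase(gene_profile: np.ndarray | pd.Series,
                 phase_profiles: pd.DataFrame) -> PhaseAssignment:
    """Assign one gene to the best-correlated phase profile.

    The gene's per-time-point mean profile is z-scored and Pearson-
    correlated with each phase profile; the argmax wins, with ties
    broken in the fixed label order.  A constant profile has no defined
    correlation and is flagged unassignable.
    """
    name = gene_profile.name if isinstance(gene_profile, pd.Series) else ""
    x = np.asarray(gene_profile, dtype=float)
    z = _zscore(x)
    cors: dict[str, float] = {}
    if np.isnan(z).all():
        return PhaseAssignment(str(name), None,
                               {p: float("nan") for p in PHASE_LABELS})
    for phase in PHASE_LABELS:
        y = phase_profiles.loc[phase].to_numpy(dtype=float)
        ok = ~(np.isnan(z) | np.isnan(y))
        if ok.sum() < 2 or y[ok].std() == 0 or z[ok].std() == 0:
            cors[phase] = float("nan")
            continue
        cors[phase] = float(np.corrcoef(z[ok], y[ok])[0, 1])
    best = max(PHASE_LABELS,
               key=lambda p: (-np.inf if np.isnan(cors[p]) else cors[p],
                              -PHASE_LABELS.index(p)))
    if np.isnan(cors[best]):
        return PhaseAssignment(str(name), None, cors)
    return PhaseAssignment(str(name), best, cors)


def assign_phases(mean_profiles: pd.DataFrame, gene_ids,
                  phase_profiles: pd.DataFrame) -> pd.DataFrame:
    """Vector version of :func:`assign_phase` over ``gene_ids``.

    Returns a DataFrame indexed by gene with the assigned phase and the
    five correlations.
    """
    rows = []
    for g in gene_ids:
        a = assign_phase(mean_profiles.loc[g], phase_profiles)
        rows.append({"gene_id": g, "phase": a.phase, **{
            f"r_{p}": a.correlations[p] for p in PHASE_LABELS}})
    return pd.DataFrame(rows).set_index("gene_id")


def markers_from_truth(truth: pd.DataFrame, n_per_phase: int = 5,
                       min_amplitude: float = 1.0,
                       arcs: dict[str, tuple[float, float]] | None = None,
                       ) -> dict[str, list[str]]:
    """Pick marker genes from simulation truth.

    For each phase label, the cyclic genes whose peak phase lies closest
    to ``n_per_phase`` anchor positions spread evenly across the label's
    arc — so wide arcs (like M/G1) get templates representing their whole
    extent, not just the midpoint.
    """
    arcs = arcs or DEFAULT_PHASE_ARCS
    cyc = truth[truth["cyclic"] & (truth["amplitude"] >= min_amplitude)]
    out: dict[str, list[str]] = {}
    for label, (a, b) in arcs.items():
        anchors = (a + (np.arange(n_per_phase) + 0.5) * (b - a) / n_per_phase) % 1.0
        picked: list[str] = []
        for m in anchors:
            d = np.minimum((cyc["peak_phase"] - m) % 1.0,
                           (m - cyc["peak_phase"]) % 1.0)
            for idx in d.nsmallest(3).index:
                g = cyc.loc[idx, "gene_id"]
                if g not in picked:
                    picked.append(g)
                    break
        out[label] = picked
    return out
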