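"""Time-course design: samples, replicates, and exclusions.

A synchronized-release experiment is a grid of (replicate, time point)
cells; every expression profile, FACS row, and ChIP signal in the
pipeline is indexed by these cells.  Individual samples can be excluded
per assay (e.g. a failed ChIP library) without touching the design
itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence


def sample_id(replicate: str, hours: float) -> str:
    """Canonical sample label, e.g. ``Epi1_12h``."""
    h = int(hours) if float(hours).is_integer() else hours
    return f"{replicate}_{h}h"


@dataclass(frozen=True)
class TimeCourseDesign:
    """Sampling grid of a synchronized time course.

    Parameters
    ----------
    time_points_hours:
        Strictly increasing collection times after release.  The default
        covers 24 h at 3 h resolution (9 points).
    replicates:
        Labels of the independent synchronization experiments.
    excluded_samples:
        ``(assay, replicate, hours)`` triples dropped from the named
        assay only.  ``assay`` is free text (e.g. ``"polII"``).
    """

    time_points_hours: tuple[float, ...] = (0, 3, 6, 9, 12, 15, 18, 21, 24)
    replicates: tuple[str, ...] = ("Epi1", "Epi2")
    excluded_samples: tuple[tuple[str, str, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        tp = tuple(float(t) for t in self.time_points_hours)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time points must be strictly increasing")
        object.__setattr__(self, "time_points_hours", tp)
        object.__setattr__(self, "replicates", tuple(self.replicates))
        for assay, rep, hours in self.excluded_samples:
            if rep not in self.replicates or float(hours) not in tp:
                raise ValueError(
                    f"excluded sample ({assay}, {rep}, {hours}) not in design"
                )

    @property
    def cells(self) -> list[tuple[str, float]]:
        """All (replicate, hours) cells, replicate-major order."""
        return [(r, t) for r in self.replicates for t in self.time_points_hours]

    @property
    def sample_ids(self) -> list[str]:
        return [sample_id(r, t) for r, t in self.cells]

    def excluded_for(self, assay: str) -> set[str]:
        """Sample ids excluded for one assay."""
        return {
            sample_id(rep, hours)
            for a, rep, hours in self.excluded_samples
            if a == assay
        }

    def kept_samples(self, assay: str | None = None) -> list[str]:
        """Sample ids retained for ``assay`` (all if assay is None)."""
        dropped = self.excluded_for(assay) if assay is not None else set()
        return [s for s in self.sample_ids if s not in dropped]

    def hours_of(self, sample: str) -> float:
        rep, h = sample.rsplit("_", 1)
        return float(h.rstrip("h"))

    def replicate_of(self, sample: str) -> str:
        return sample.rsplit("_", 1)[0]


def default_design(exclude_polii_12h_epi2: bool = True) -> TimeCourseDesign:
    """The study layout: 0-24 h every 3 h, two replicates.

    By default the Pol II sample (12 h, Epi2) is excluded, mirroring the
    technical failure identified by western blot in the source data.
    """
    excl: Sequence[tuple[str, str, float]] = ()
    if exclude_polii_12h_epi2:
        excl = (("polII", "Epi2", 12.0),)
    return TimeCourseDesign(excluded_samples=tuple(excl))
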