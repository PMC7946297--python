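"""Transect survey designs for acoustic road-gradient studies.

A survey design is the sampling frame of a distance-gradient acoustic study:
a set of transects (low-traffic side roads running perpendicular to a
freeway), each carrying one detector per distance interval, each detector
recording for a number of whole nights.  The observation unit downstream is
the detector-night.  Equipment failure and unsuitable detector sites mean
not every cell of the frame is realized in the field, so each cell carries a
``realized`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Detector distances (metres from the freeway edge) used in the central
#: Victoria freeway surveys.  The first interval is nominally 0-10 m; the
#: detector sat wherever a suitable tree stood, and 10 m is used as its
#: nominal distance.
STUDY_DISTANCES_M: tuple[float, ...] = (10, 25, 50, 75, 100, 250, 500, 1000, 1500, 2000)

#: Number of detector-nights actually realized per distance in the study
#: (out of 36 possible at each distance: 18 transects x 2 nights).
#: The counts sum to 280 of the potential 360 cells.
STUDY_MISSINGNESS: dict[float, int] = {
    10: 29, 25: 21, 50: 22, 75: 32, 100: 30,
    250: 26, 500: 36, 1000: 28, 1500: 32, 2000: 24,
}

#: Default transect-to-freeway allocation (5 + 6 + 7 = 18 transects).
STUDY_FREEWAYS: tuple[tuple[str, int], ...] = (
    ("Calder", 5), ("Goulburn Valley", 6), ("Hume", 7),
)

DESIGN_COLUMNS = ["transect_id", "freeway", "distance_m", "night_id", "realized"]


class InvalidDesignError(ValueError):
    """Raised when a requested sampling frame is not a valid design."""


@dataclass
class SurveyDesign:
    """A transect x distance x night sampling frame.

    Attributes
    ----------
    frame : pandas.DataFrame
        One row per cell with columns ``transect_id``, ``freeway``,
        ``distance_m``, ``night_id`` and boolean ``realized``.
    distances_m : tuple of float
        The ordered sampling distances (strictly increasing, all >= 0).
    """

    frame: pd.DataFrame
    distances_m: tuple[float, ...] = field(default=STUDY_DISTANCES_M)

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_m, dtype=float)
        if d.size == 0 or np.any(d < 0) or np.any(np.diff(d) <= 0):
            raise InvalidDesignError(
                "distances must be nonnegative and strictly increasing, got "
                f"{list(self.distances_m)}"
            )
        missing = set(DESIGN_COLUMNS) - set(self.frame.columns)
        if missing:
            raise InvalidDesignError(f"design frame lacks columns {sorted(missing)}")

    @property
    def n_cells(self) -> int:
        return len(self.frame)

    @property
    def n_realized(self) -> int:
        return int(self.frame["realized"].sum())

    @property
    def transects(self) -> list[str]:
        return list(pd.unique(self.frame["transect_id"]))

    def realized_cells(self) -> pd.DataFrame:
        """The realized detector-night cells, one row each."""
        return self.frame.loc[self.frame["realized"]].reset_index(drop=True)


def _freeway_labels(n_transects: int) -> list[str]:
    """Allocate transects to freeways following the study's 5/6/7 split,
    cycling for designs larger than 18 transects."""
    labels: list[str] = []
    while len(labels) < n_transects:
        for name, count in STUDY_FREEWAYS:
            labels.extend([name] * count)
    return labels[:n_transects]


def build_design(
    n_transects: int,
    distances_m: Sequence[float] = STUDY_DISTANCES_M,
    n_nights: int = 2,
) -> SurveyDesign:
    """Build the full-factorial transect x distance x night frame.

    All cells are marked realized; use :func:`apply_missingness` to thin
    the frame to a field-realistic subset.

    Parameters
    ----------
    n_transects : int
        Number of transects (default study design uses 18).
    distances_m : sequence of float
        Strictly increasing nonnegative detector distances.
    n_nights : int
        Consecutive recording nights per transect (study: 2).
    """
    if n_transects < 1 or n_nights < 1:
        raise InvalidDesignError("n_transects and n_nights must be positive")
    d = np.asarray(list(distances_m), dtype=float)
    if d.size == 0 or np.any(d < 0) or np.any(np.diff(d) <= 0):
        raise InvalidDesignError(
            "distances must be nonnegative and strictly increasing"
        )
    transect_ids = [f"T{i + 1:02d}" for i in range(n_transects)]
    freeways = dict(zip(transect_ids, _freeway_labels(n_transects)))
    frame = pd.DataFrame(
        [
            (t, freeways[t], dist, night, True)
            for t in transect_ids
            for dist in d
            for night in range(1, n_nights + 1)
        ],
        columns=DESIGN_COLUMNS,
    )
    return SurveyDesign(frame=frame, distances_m=tuple(d.tolist()))


def apply_missingness(
    design: SurveyDesign,
    per_distance_n: Mapping[float, int],
    seed: int | np.random.Generator = 0,
) -> SurveyDesign:
    """Thin a design to a fixed number of realized cells per distance.

    For each distance the retained cells are chosen uniformly at random
    without replacement among that distance's cells, so the realized pattern
    is exactly reproducible under a fixed seed.  ``STUDY_MISSINGNESS``
    reproduces the study's 280-of-360 pattern.

    Raises
    ------
    InvalidDesignError
        If a requested count exceeds the cells available at that distance.
    """
    rng = np.random.default_rng(seed)
    frame = design.frame.copy()
    realized = frame["realized"].to_numpy().copy()
    for dist, keep in per_distance_n.items():
        idx = np.flatnonzero(frame["distance_m"].to_numpy() == float(dist))
        if keep > idx.size:
            raise InvalidDesignError(
                f"cannot retain {keep} cells at {dist} m: only {idx.size} available"
            )
        if keep < 0:
            raise InvalidDesignError(f"negative retained count at {dist} m")
        realized[idx] = False
        realized[rng.choice(idx, size=keep, replace=False)] = True
    frame["realized"] = realized
    return SurveyDesign(frame=frame, distances_m=design.distances_m)


def study_design(seed: int = 0) -> SurveyDesign:
    """The default 18-transect, 10-distance, 2-night design thinned to the
    study's realized 280 detector-nights."""
    return apply_missingness(build_design(18, STUDY_DISTANCES_M, 2),
                             STUDY_MISSINGNESS, seed=seed)
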