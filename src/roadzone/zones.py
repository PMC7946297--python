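"""Road-effect-zone distances from fitted activity-distance coefficients.

Under the activity model, predicted call activity at mean covariates is
``exp(beta0 + beta1 * log10(d + 1))``, which for beta1 > 0 increases
monotonically with distance d from the freeway, so its maximum over the
sampled range [0, d_max] sits at d_max.  The road-effect zone at a decline
threshold p is the distance within which activity is depressed by at least
a fraction p relative to that maximum, i.e. the d solving

    activity(d) = (1 - p) * activity(d_max).

Because activity(d) is proportional to (d + 1)^(beta1 / ln 10), the
boundary has the closed form

    d = (d_max + 1) * (1 - p)^(ln 10 / beta1) - 1,

reported to the nearest metre.  A species whose activity does not decline
toward the road (beta1 <= 0), or whose boundary falls below one metre, has
no road-effect zone at that threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .simulate import CoefficientSet

__all__ = [
    "ZoneQuery", "predicted_activity", "zone_closed_form", "zone_numeric",
    "invert_zone", "zone_table", "render_zone_table", "consistency_check",
    "load_reference_zones", "DEFAULT_THRESHOLDS", "DEFAULT_D_MAX",
]

LN10 = math.log(10.0)

#: Decline thresholds of the published multi-threshold zone table, in the
#: order its columns are printed (largest decline first).
DEFAULT_THRESHOLDS: tuple[float, ...] = (0.50, 0.30, 0.25, 0.20, 0.15, 0.10)

#: Farthest sampled distance in the study design (metres).
DEFAULT_D_MAX: float = 2000.0

NONE_CELL = "-"


@dataclass(frozen=True)
class ZoneQuery:
    """One zone evaluation: distance coefficient, fractional decline
    threshold in [0, 1), and the farthest sampled distance d_max."""

    beta1: float
    decline_p: float = 0.20
    d_max: float = DEFAULT_D_MAX

    def __post_init__(self) -> None:
        if not 0.0 <= self.decline_p < 1.0:
            raise ValueError("decline_p must lie in [0, 1)")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def predicted_activity(
    coefs: CoefficientSet | float, distance_m: float | np.ndarray
) -> float | np.ndarray:
    """Model-predicted call rate at a distance, covariates at their
    reference (mean) values and transect effect zero.

    Accepts a full :class:`CoefficientSet` or a bare beta1 (beta0 = 0;
    zone boundaries do not depend on beta0).
    """
    if isinstance(coefs, CoefficientSet):
        beta0, beta1 = coefs.beta0, coefs.beta1
    else:
        beta0, beta1 = 0.0, float(coefs)
    d = np.asarray(distance_m, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance_m must be >= 0")
    out = np.exp(beta0 + beta1 * np.log10(d + 1.0))
    return float(out) if out.ndim == 0 else out


def zone_closed_form(
    beta1: float | ZoneQuery,
    decline_p: float = 0.20,
    d_max: float = DEFAULT_D_MAX,
) -> int | None:
    """Road-effect-zone boundary in whole metres, or None.

    Solves activity(d) = (1 - p) * activity(d_max) analytically; rounds to
    the nearest metre (half away from zero).  Returns None when beta1 <= 0
    (no decline toward the road) or the unrounded boundary is below 1 m.
    At p = 0 the boundary is d_max itself.
    """
    q = beta1 if isinstance(beta1, ZoneQuery) else ZoneQuery(float(beta1), decline_p, d_max)
    if q.beta1 <= 0:
        return None
    if q.decline_p == 0.0:
        return _round_half_away(q.d_max)
    d = (q.d_max + 1.0) * (1.0 - q.decline_p) ** (LN10 / q.beta1) - 1.0
    if d < 1.0:
        return None
    return _round_half_away(d)


def zone_numeric(
    coefs: CoefficientSet | float,
    decline_p: float = 0.20,
    d_max: float = DEFAULT_D_MAX,
    step: float = 0.1,
) -> int | None:
    """Grid-search zone boundary: independent check of the closed form.

    Evaluates predicted activity on a ``step``-metre grid over [0, d_max],
    takes the grid maximum, and returns the largest grid distance at which
    activity is at or below (1 - p) times that maximum, rounded to the
    nearest metre; None when no grid point qualifies or the boundary is
    below 1 m.
    """
    if not 0.0 <= decline_p < 1.0:
        raise ValueError("decline_p must lie in [0, 1)")
    beta1 = coefs.beta1 if isinstance(coefs, CoefficientSet) else float(coefs)
    if beta1 <= 0:
        return None
    grid = np.arange(0.0, d_max + step / 2, step)
    act = predicted_activity(coefs, grid)
    threshold = (1.0 - decline_p) * act.max()
    below = np.flatnonzero(act <= threshold)
    if below.size == 0:
        return None
    d = grid[below[-1]]
    if d < 1.0:
        return None
    return _round_half_away(float(d))


def invert_zone(
    distance_m: float, decline_p: float, d_max: float = DEFAULT_D_MAX
) -> float:
    """The beta1 whose zone boundary at ``decline_p`` is ``distance_m``.

    Algebraic inverse of the closed form:
    beta1 = ln 10 * ln(1 - p) / ln((d + 1) / (d_max + 1)).
    """
    if not 0.0 < decline_p < 1.0:
        raise ValueError("decline_p must lie in (0, 1)")
    if not 0.0 < distance_m < d_max:
        raise ValueError("distance_m must lie strictly between 0 and d_max")
    return LN10 * math.log(1.0 - decline_p) / math.log((distance_m + 1.0) / (d_max + 1.0))


def zone_table(
    beta1_map: Mapping[str, float | None],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    d_max: float = DEFAULT_D_MAX,
) -> pd.DataFrame:
    """Multi-threshold zone table, one row per species.

    ``beta1_map`` maps row label (species, or "all species combined") to
    its posterior-mean distance coefficient (None is treated as no
    decline).  Columns are labelled with the thresholds as percentages;
    cells hold whole metres or NaN where no zone exists.
    """
    cols = [f"{int(round(p * 100))}%" for p in thresholds]
    rows = {}
    for label, b1 in beta1_map.items():
        rows[label] = [
            zone_closed_form(b1, p, d_max) if b1 is not None else None
            for p in thresholds
        ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    table.index.name = "species"
    return table.astype("float64")


def render_zone_table(table: pd.DataFrame) -> str:
    """Aligned text rendering with '-' for absent zones."""
    shown = table.copy()
    for c in shown.columns:
        shown[c] = [NONE_CELL if pd.isna(v) else str(int(v)) for v in shown[c]]
    return shown.reset_index().to_string(index=False)


def consistency_check(
    zone_row: Mapping[float, float | None] | Sequence[float | None],
    thresholds: Sequence[float] | None = None,
    d_max: float = DEFAULT_D_MAX,
) -> dict:
    """Check that one species' multi-threshold zone distances are mutually
    consistent with a single distance coefficient.

    Inverts every numeric cell to a beta1 and reports the relative spread
    (max - min) / mean.  A row printed to the nearest metre from one
    coefficient spreads well under 2%.

    Returns a dict with ``beta1_values``, ``spread`` and ``consistent``
    (spread < 0.02).  Raises ``ValueError`` with fewer than two numeric
    cells.
    """
    if isinstance(zone_row, Mapping):
        pairs = list(zone_row.items())
    else:
        if thresholds is None:
            raise ValueError("thresholds required when zone_row is a sequence")
        pairs = list(zip(thresholds, zone_row))
    betas = {
        p: invert_zone(float(d), float(p), d_max)
        for p, d in pairs
        if d is not None and not (isinstance(d, float) and math.isnan(d))
    }
    if len(betas) < 2:
        raise ValueError("consistency check needs at least two numeric cells")
    vals = np.array(list(betas.values()))
    spread = float((vals.max() - vals.min()) / vals.mean())
    return {"beta1_values": betas, "spread": spread, "consistent": spread < 0.02}


def load_reference_zones() -> pd.DataFrame:
    """The published multi-threshold road-effect-zone table for the ten
    bat species of the central Victoria freeway study (regression
    fixture).  NaN marks '-' cells (no zone at that threshold)."""
    with resources.files("roadzone.data").joinpath("reference_zones.csv").open() as fh:
        table = pd.read_csv(fh, index_col="species", comment="#")
    table.columns = [c.strip() for c in table.columns]
    return table
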