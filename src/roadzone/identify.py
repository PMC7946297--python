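"""Call-validity filtering, species identification and nightly aggregation.

Automated bat-call classification assigns each echolocation pulse within a
recorded call sequence to a species (or leaves it unassigned).  To limit
misidentification, a call is only attempted when it holds at least five
valid pulses, and is accepted only when a strict majority (>50%) of its
pulses agree on one species; everything else is "unknown".  Species whose
calls cannot be told apart are pooled into a complex before the vote —
here the two long-eared Nyctophilus species and the large-footed myotis
form the Nyctophilus-Myotis complex.

Identified calls are then counted per detector-night and species: the
response variable of the activity model.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .design import SurveyDesign
from .simulate import RECORD_COLUMNS, CovariateTable

UNKNOWN = "unknown"
UNASSIGNED = "unassigned"

NYCTOPHILUS_MYOTIS = "Nyctophilus-Myotis complex"

#: Taxa pooled because their calls are not reliably separable.
DEFAULT_COMPLEX_MAP: dict[str, str] = {
    "Nyctophilus geoffroyi": NYCTOPHILUS_MYOTIS,
    "Nyctophilus gouldi": NYCTOPHILUS_MYOTIS,
    "Myotis macropus": NYCTOPHILUS_MYOTIS,
}

#: The ten species / species complexes of the central Victoria assemblage,
#: post complex-pooling.
DEFAULT_SPECIES: tuple[str, ...] = (
    "Austronomus australis",
    "Chalinolobus gouldii",
    "Chalinolobus morio",
    NYCTOPHILUS_MYOTIS,
    "Ozimops ridei",
    "Ozimops planiceps",
    "Scotorepens balstoni",
    "Vespadelus darlingtoni",
    "Vespadelus regulus",
    "Vespadelus vulturnus",
)

#: All raw labels a classifier may emit under the default taxonomy.
DEFAULT_TAXA: tuple[str, ...] = tuple(
    s for s in DEFAULT_SPECIES if s != NYCTOPHILUS_MYOTIS
) + tuple(DEFAULT_COMPLEX_MAP)


def group_complex(
    species_label: str, complex_map: Mapping[str, str] | None = None
) -> str:
    """Map a raw taxon label through the species-complex pooling; labels
    outside the map (including "unassigned") map to themselves."""
    cmap = DEFAULT_COMPLEX_MAP if complex_map is None else complex_map
    return cmap.get(species_label, species_label)


class CallIdentifier(BaseEstimator, TransformerMixin):
    """Stateless transformer from pulse tables to identified calls.

    Parameters
    ----------
    species : iterable of str
        The configured species list (post-pooling); any pulse label that
        maps outside this list and is not "unassigned" raises an error.
    complex_map : mapping or None
        Raw-label -> pooled-label map applied per pulse before the
        majority vote (None selects the default Nyctophilus-Myotis map).
    min_pulses : int
        Minimum pulses for identification to be attempted (default 5).
    majority : float
        Fraction of pulses one species must strictly exceed (default 0.5).
    """

    def __init__(
        self,
        species: Iterable[str] = DEFAULT_SPECIES,
        complex_map: Mapping[str, str] | None = None,
        min_pulses: int = 5,
        majority: float = 0.5,
    ) -> None:
        self.species = species
        self.complex_map = complex_map
        self.min_pulses = min_pulses
        self.majority = majority

    def fit(self, X: pd.DataFrame | None = None, y=None) -> "CallIdentifier":
        """No-op (the identifier learns nothing); kept for pipeline use."""
        self.n_features_in_ = 0 if X is None else X.shape[1]
        return self

    def _identify_one(self, n_pulses: int, labels: list[str]) -> str:
        if len(labels) != n_pulses or n_pulses < 1:
            raise ValueError(
                f"malformed call: n_pulses={n_pulses} with {len(labels)} labels"
            )
        cmap = DEFAULT_COMPLEX_MAP if self.complex_map is None else self.complex_map
        species = set(self.species)
        mapped = [group_complex(lab, cmap) for lab in labels]
        bad = {m for m in mapped if m != UNASSIGNED and m not in species}
        if bad:
            raise ValueError(f"pulse labels outside configured species list: {sorted(bad)}")
        if n_pulses < self.min_pulses:
            return UNKNOWN
        counts = pd.Series([m for m in mapped if m != UNASSIGNED]).value_counts()
        if len(counts) and counts.iloc[0] > self.majority * n_pulses:
            return str(counts.index[0])
        return UNKNOWN

    def transform(self, pulse_table: pd.DataFrame) -> pd.DataFrame:
        """Identify every call of a pulse table.

        Returns a frame with ``call_id``, the location key columns, and
        ``species`` (a configured species or "unknown").  Any ``confirmed``
        column (the manual visual check for Austronomus australis files)
        is carried through unchanged.
        """
        out = pulse_table[
            ["call_id", "transect_id", "distance_m", "night_id"]
        ].copy()
        out["species"] = [
            self._identify_one(int(n), str(a).split(";"))
            for n, a in zip(pulse_table["n_pulses"], pulse_table["pulse_assignments"])
        ]
        if "confirmed" in pulse_table.columns:
            out["confirmed"] = pulse_table["confirmed"].to_numpy()
        return out


def identify_call(
    n_pulses: int,
    pulse_assignments: Iterable[str],
    complex_map: Mapping[str, str] | None = None,
    species: Iterable[str] = DEFAULT_SPECIES,
    min_pulses: int = 5,
) -> str:
    """Identify a single call; see :class:`CallIdentifier`."""
    ident = CallIdentifier(species=species, complex_map=complex_map,
                           min_pulses=min_pulses)
    return ident._identify_one(int(n_pulses), list(pulse_assignments))


def aggregate_nightly(
    identified: pd.DataFrame,
    design: SurveyDesign,
    covariates: CovariateTable,
    species: Iterable[str] = DEFAULT_SPECIES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Count identified calls per realized detector-night and species.

    Returns ``(records, unknown_summary)``: one record per realized cell x
    species with zero-filled counts and attached covariates (the model's
    input table), plus a per-cell summary of "unknown" calls, which are
    excluded from the species records.

    Raises
    ------
    ValueError
        If any call sits at a cell the design did not realize.
    """
    cells = covariates.attach(design.realized_cells())
    key = ["transect_id", "distance_m", "night_id"]
    if len(identified):
        # align key dtypes with the design frame (e.g. int vs float metres)
        identified = identified.astype({k: cells[k].dtype for k in key})
    cell_index = pd.MultiIndex.from_frame(cells[key])
    if len(identified):
        call_index = pd.MultiIndex.from_frame(identified[key])
        stray = ~call_index.isin(cell_index)
        if stray.any():
            raise ValueError(
                "calls recorded at unrealized design cells: "
                f"{sorted(set(call_index[stray]))[:5]}"
            )
    species = list(species)
    known = identified[identified["species"] != UNKNOWN] if len(identified) else identified
    extra = set(known["species"]) - set(species) if len(known) else set()
    if extra:
        warnings.warn(f"identified species outside requested list ignored: {sorted(extra)}")
    counts = (
        known.groupby(key + ["species"]).size() if len(known)
        else pd.Series(dtype=int)
    )
    grid = cells.loc[cells.index.repeat(len(species))].reset_index(drop=True)
    grid["species"] = np.tile(np.asarray(species, dtype=object), len(cells))
    grid_key = pd.MultiIndex.from_frame(grid[key + ["species"]])
    grid["n_calls"] = counts.reindex(grid_key, fill_value=0).to_numpy()
    unknown = identified[identified["species"] == UNKNOWN] if len(identified) else identified
    unknown_summary = (
        unknown.groupby(key).size().rename("n_unknown").reset_index()
        if len(unknown) else pd.DataFrame(columns=key + ["n_unknown"])
    )
    return grid[RECORD_COLUMNS], unknown_summary
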