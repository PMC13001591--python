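"""Grouped abundance series and the predation-potential score.

Predation potential is a consumption-weighted community abundance: each
species' captures are multiplied by ``consumption_rate / 100`` (its average
daily aphid consumption scaled so that a 100-aphid/day species has weight 1)
and summed.  It estimates the ceiling of aphid-suppression capacity, not
realized predation — no density dependence, prey switching, or intraguild
interactions are modeled.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .ingest import GROUP_KEYS
from .species import HabitatMap, SpeciesRegistry

#: The four community-level metrics analyzed throughout.
COMMUNITY_METRICS = ("native", "exotic", "all", "predation")


class PredationWeights:
    """Per-species predation weights ``w_s = consumption_rate_s / 100``."""

    def __init__(self, weights: Mapping[str, float]):
        bad = {s: w for s, w in weights.items() if w < 0}
        if bad:
            raise ValueError(f"negative predation weights: {bad}")
        self._w = dict(weights)

    def __getitem__(self, species: str) -> float:
        try:
            return self._w[species]
        except KeyError:
            raise KeyError(f"no predation weight configured for species {species!r}") from None

    def __contains__(self, species: str) -> bool:
        return species in self._w

    def as_dict(self) -> dict[str, float]:
        return dict(self._w)

    @classmethod
    def from_registry(cls, registry: SpeciesRegistry) -> "PredationWeights":
        return cls({name: registry.predation_weight(name) for name in registry.names})


def predation_potential(
    per_species_captures: Mapping[str, float], weights: PredationWeights
) -> float:
    """Consumption-weighted capture total: ``sum_s captures_s * w_s``.

    Linear in captures; an observed species with positive count must have a
    configured weight.
    """
    total = 0.0
    for species, captures in per_species_captures.items():
        if captures == 0:
            continue
        total += captures * weights[species]
    return total


def series_by_group(
    aggregates: pd.DataFrame,
    habitat_map: HabitatMap,
    group: str,
    weights: PredationWeights | None = None,
) -> pd.DataFrame:
    """Per-unit response series for one community metric or species.

    Parameters
    ----------
    aggregates : the SampleAggregate table (per-species and group rows).
    habitat_map : treatment -> habitat class; every treatment in the data
        must resolve (configuration error otherwise).
    group : ``native``, ``exotic``, ``all``, ``predation``, or a species name.
    weights : required when ``group == "predation"``.

    Returns
    -------
    DataFrame with columns (treatment, replicate, year, habitat, response,
    effort); the habitat-partitioned view is a column selection, the pooled
    view simply ignores ``habitat``.  Predation effort reuses the all-species
    group effort (the score is a community measure over the same trap set).
    """
    unit = ["treatment", "replicate", "year"]
    if group == "predation":
        if weights is None:
            raise ValueError("predation series requires PredationWeights")
        species_rows = aggregates[~aggregates["taxon_key"].isin(GROUP_KEYS)].copy()
        w = species_rows["taxon_key"].map(weights.as_dict())
        missing = species_rows.loc[w.isna() & (species_rows["captures"] > 0), "taxon_key"]
        if len(missing):
            raise KeyError(f"no predation weight for species: {sorted(missing.unique())}")
        species_rows["response"] = species_rows["captures"] * w.fillna(0.0)
        resp = species_rows.groupby(unit, observed=True, sort=True)["response"].sum()
        eff = (
            aggregates[aggregates["taxon_key"] == "all"]
            .set_index(unit)["effort"]
        )
        out = pd.DataFrame({"response": resp}).join(eff).reset_index()
    else:
        rows = aggregates[aggregates["taxon_key"] == group]
        if rows.empty:
            raise ValueError(f"no aggregate rows for group {group!r}")
        out = rows.rename(columns={"captures": "response"})[unit + ["response", "effort"]].copy()

    missing_treatments = [t for t in out["treatment"].unique() if t not in habitat_map]
    if missing_treatments:
        raise KeyError(f"treatments absent from habitat map: {sorted(missing_treatments)}")
    out["habitat"] = out["treatment"].map(lambda t: habitat_map[t])
    out["response"] = out["response"].astype(float)
    return out[unit[:2] + ["year", "habitat", "response", "effort"]].reset_index(drop=True)
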