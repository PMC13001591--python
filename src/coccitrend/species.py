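"""Species registry and treatment-to-habitat mapping.

The study community is the 14 Coccinellidae taxa monitored at a long-term
cropping-systems experiment: 10 native species and 4 exotic (adventive)
species.  Each species carries an origin label and a daily aphid consumption
rate (aphids/day) that feeds the predation-potential weighting
(``weight = consumption_rate / 100``).

The default consumption rates shipped here are synthetic stand-ins of
literature-plausible magnitude: the study's own constants are not printed in
its text.  Replace them via a YAML config for any quantitative use against
real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

HABITATS = ("annual", "perennial", "forest")


class Origin(str, Enum):
    NATIVE = "native"
    EXOTIC = "exotic"


def _canon(name: str) -> str:
    """Canonical species key: whitespace-trimmed, case-folded. No fuzzy matching."""
    return " ".join(name.split()).casefold()


@dataclass(frozen=True)
class SpeciesInfo:
    name: str
    origin: Origin
    consumption_rate: float  # aphids/day, >= 0

    def __post_init__(self):
        if self.consumption_rate < 0:
            raise ValueError(f"consumption_rate must be >= 0, got {self.consumption_rate}")


class SpeciesRegistry:
    """Lookup table of species origin and consumption rate.

    Matching is exact after whitespace trim and case fold; an unknown species
    raises ``KeyError`` naming the offending label.
    """

    def __init__(self, species: Iterable[SpeciesInfo]):
        self._by_key: dict[str, SpeciesInfo] = {}
        for sp in species:
            key = _canon(sp.name)
            if key in self._by_key:
                raise ValueError(f"duplicate species entry: {sp.name!r}")
            self._by_key[key] = sp
        if not self._by_key:
            raise ValueError("registry must contain at least one species")

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, name: str) -> bool:
        return _canon(name) in self._by_key

    def __getitem__(self, name: str) -> SpeciesInfo:
        key = _canon(name)
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"species {name!r} not found in registry") from None

    @property
    def names(self) -> list[str]:
        return [sp.name for sp in self._by_key.values()]

    def names_by_origin(self, origin: Origin | str) -> list[str]:
        origin = Origin(origin)
        return [sp.name for sp in self._by_key.values() if sp.origin is origin]

    def origin(self, name: str) -> Origin:
        return self[name].origin

    def consumption_rate(self, name: str) -> float:
        return self[name].consumption_rate

    def predation_weight(self, name: str) -> float:
        """Per-capture predation weight: daily aphid consumption / 100."""
        return self[name].consumption_rate / 100.0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            sp.name: {"origin": sp.origin.value, "consumption_rate": sp.consumption_rate}
            for sp in self._by_key.values()
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping]) -> "SpeciesRegistry":
        return cls(
            SpeciesInfo(name, Origin(v["origin"]), float(v["consumption_rate"]))
            for name, v in d.items()
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SpeciesRegistry":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc["species"])


class HabitatMap:
    """Total map from treatment label to habitat class (annual/perennial/forest)."""

    def __init__(self, mapping: Mapping[str, str]):
        bad = {t: h for t, h in mapping.items() if h not in HABITATS}
        if bad:
            raise ValueError(f"unknown habitat classes: {bad}; expected one of {HABITATS}")
        self._map = dict(mapping)

    def __getitem__(self, treatment: str) -> str:
        try:
            return self._map[treatment]
        except KeyError:
            raise KeyError(f"treatment {treatment!r} has no habitat assignment") from None

    def __contains__(self, treatment: str) -> bool:
        return treatment in self._map

    @property
    def treatments(self) -> list[str]:
        return list(self._map)

    def to_dict(self) -> dict:
        return dict(self._map)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "HabitatMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls({t: v["habitat"] if isinstance(v, dict) else v for t, v in doc["treatments"].items()})


# ---------------------------------------------------------------------------
# Study defaults

#: Daily aphid consumption rates (aphids/day).  SYNTHETIC STAND-INS of
#: plausible magnitude for adult coccinellids; the study's constants are
#: config inputs, not printed values.
_STUDY_SPECIES: list[tuple[str, str, float]] = [
    # natives
    ("Adalia bipunctata", "native", 50.0),
    ("Brachiacantha ursina", "native", 20.0),
    ("Chilocorus stigma", "native", 30.0),
    ("Coccinella trifasciata", "native", 40.0),
    ("Coleomegilla maculata", "native", 50.0),
    ("Cycloneda munda", "native", 40.0),
    ("Hippodamia convergens", "native", 60.0),
    ("Hippodamia glacialis", "native", 60.0),
    ("Hippodamia parenthesis", "native", 30.0),
    ("Hippodamia tredecimpunctata", "native", 50.0),
    # exotics
    ("Coccinella septempunctata", "exotic", 110.0),
    ("Harmonia axyridis", "exotic", 100.0),
    ("Hippodamia variegata", "exotic", 60.0),
    ("Propylea quatuordecimpunctata", "exotic", 40.0),
]

#: 10 plant-community treatments: four annual row-crop systems, three
#: perennial systems, three forest systems.
_STUDY_TREATMENTS: dict[str, str] = {
    "T1": "annual",       # conventional corn-soybean-wheat
    "T2": "annual",       # no-till
    "T3": "annual",       # reduced input
    "T4": "annual",       # biologically based
    "T5": "perennial",    # poplar plantation
    "T6": "perennial",    # alfalfa
    "T7": "perennial",    # early successional
    "CF": "forest",       # coniferous plantation
    "DF": "forest",       # late successional deciduous forest
    "SF": "forest",       # mid-successional forest
}


def study_registry() -> SpeciesRegistry:
    """The 14-species registry (10 native, 4 exotic) with stand-in consumption rates."""
    return SpeciesRegistry(
        SpeciesInfo(n, Origin(o), c) for n, o, c in _STUDY_SPECIES
    )


def study_habitat_map() -> HabitatMap:
    """The 10-treatment map onto the three habitat classes."""
    return HabitatMap(_STUDY_TREATMENTS)


def write_study_config(path: str | Path) -> None:
    """Write the default species + treatment config as YAML."""
    doc = {
        "species": study_registry().to_dict(),
        "treatments": {t: {"habitat": h} for t, h in _STUDY_TREATMENTS.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
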