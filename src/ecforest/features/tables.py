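"""Physicochemical reference tables and the feature schema.

All numeric tables are shipped as versioned JSON data files next to this
module and validated on load:

- ``physico_tables.json`` — average residue masses, Dayhoff background
  frequencies (relative occurrence per 1000 residues normalized to 100),
  Kyte-Doolittle hydropathy, elemental composition of the free amino acids,
  property-class residue sets, per-residue charge, and two pKa sets
  (``emboss`` default, ``bjellqvist`` alternative with residue-specific
  terminal adjustments).
- ``diwv.json`` — the 400-entry dipeptide instability weight table.
- ``schema_73.json`` — the default 73-feature schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from typing import Dict, FrozenSet, List, Tuple

STANDARD_RESIDUES: Tuple[str, ...] = tuple(sorted("ACDEFGHIKLMNPQRSTVWY"))


def _load_json(name: str) -> dict:
    ref = resources.files(__package__).joinpath("data", name)
    with ref.open(encoding="utf-8") as handle:
        return json.load(handle)


@dataclass(frozen=True)
class PKaSet:
    name: str
    nterm: float
    cterm: float
    side_chain: Dict[str, float]       # K, R, H (positive); D, E, C, Y (negative)
    nterm_by_residue: Dict[str, float]
    cterm_by_residue: Dict[str, float]

    POSITIVE = ("K", "R", "H")
    NEGATIVE = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PhysicoChemicalTables:
    """Container for every residue-level constant the feature ops need."""

    version: str
    water_mass: float
    residue_avg_mass: Dict[str, float]
    dayhoff_freq: Dict[str, float]
    kyte_doolittle: Dict[str, float]
    elemental: Dict[str, Tuple[int, ...]]  # (C, H, N, O, S) of the free amino acid
    water_atoms: Tuple[int, ...]
    property_classes: Dict[str, FrozenSet[str]]
    residue_charge: Dict[str, float]
    diwv: Dict[str, Dict[str, float]]
    pka: PKaSet

    def validate(self) -> "PhysicoChemicalTables":
        for name, table in (
            ("residue_avg_mass", self.residue_avg_mass),
            ("dayhoff_freq", self.dayhoff_freq),
            ("kyte_doolittle", self.kyte_doolittle),
            ("elemental", self.elemental),
            ("residue_charge", self.residue_charge),
        ):
            missing = set(STANDARD_RESIDUES) - set(table)
            if missing:
                raise ValueError(f"table {name} is missing residues {sorted(missing)}")
        if any(v <= 0 for v in self.dayhoff_freq.values()):
            raise ValueError("dayhoff frequencies must be strictly positive")
        for a in STANDARD_RESIDUES:
            row = self.diwv.get(a)
            if row is None or set(row) != set(STANDARD_RESIDUES):
                raise ValueError(f"diwv table incomplete for residue {a}")
        return self


def load_tables(pka_set: str = "emboss") -> PhysicoChemicalTables:
    raw = _load_json("physico_tables.json")
    diwv = _load_json("diwv.json")
    try:
        pk_raw = raw["pka_sets"][pka_set]
    except KeyError as exc:
        raise ValueError(
            f"unknown pKa set {pka_set!r}; available: {sorted(raw['pka_sets'])}"
        ) from exc
    pka = PKaSet(
        name=pka_set,
        nterm=pk_raw["nterm"],
        cterm=pk_raw["cterm"],
        side_chain={r: pk_raw[r] for r in PKaSet.POSITIVE + PKaSet.NEGATIVE},
        nterm_by_residue=dict(pk_raw.get("nterm_by_residue", {})),
        cterm_by_residue=dict(pk_raw.get("cterm_by_residue", {})),
    )
    tables = PhysicoChemicalTables(
        version=raw["version"],
        water_mass=raw["water_mass"],
        residue_avg_mass=raw["residue_avg_mass"],
        dayhoff_freq=raw["dayhoff_freq"],
        kyte_doolittle=raw["kyte_doolittle"],
        elemental={r: tuple(v) for r, v in raw["elemental"].items()},
        water_atoms=tuple(raw["water_atoms"]),
        property_classes={
            name: frozenset(members)
            for name, members in raw["property_classes"].items()
        },
        residue_charge=raw["residue_charge"],
        diwv=diwv,
        pka=pka,
    )
    return tables.validate()


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with group tags; default version ``73-v1``."""

    version: str
    names: Tuple[str, ...]
    kinds: Dict[str, str]  # composition | order | global

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def load_schema() -> FeatureSchema:
    raw = _load_json("schema_73.json")
    names = tuple(f["name"] for f in raw["features"])
    if len(set(names)) != len(names):
        raise ValueError("schema contains duplicate feature names")
    return FeatureSchema(
        version=raw["version"],
        names=names,
        kinds={f["name"]: f["kind"] for f in raw["features"]},
    )
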