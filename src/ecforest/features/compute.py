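"""Sequence-derived physicochemical feature computations.

Each operation takes a validated residue string (uppercase, 20-letter
standard alphabet) plus the reference tables and returns plain numbers.
:func:`extract_features` assembles the full schema vector;
:func:`extract_table` builds a table over many records.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Dict, Iterable, List, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from ..records import ProteinRecord
from .tables import (
    STANDARD_RESIDUES,
    FeatureSchema,
    PhysicoChemicalTables,
    load_schema,
    load_tables,
)


def _check_nonempty(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")


def mole_percent(seq: str) -> Dict[str, float]:
    """Amino acid composition: ``100 * count(r) / length`` for each residue."""
    _check_nonempty(seq)
    counts = Counter(seq)
    length = len(seq)
    return {r: 100.0 * counts.get(r, 0) / length for r in STANDARD_RESIDUES}


def dayhoffstat(seq: str, tables: PhysicoChemicalTables) -> Dict[str, float]:
    """Molar percentage divided by the Dayhoff background statistic (the
    residue's relative occurrence per 1000 amino acids normalized to 100)."""
    mp = mole_percent(seq)
    return {r: mp[r] / tables.dayhoff_freq[r] for r in STANDARD_RESIDUES}


def molecular_weight(seq: str, tables: PhysicoChemicalTables) -> float:
    """Average molecular weight: sum of free amino acid masses minus one
    water per peptide bond."""
    _check_nonempty(seq)
    total = sum(tables.residue_avg_mass[r] for r in seq)
    return total - (len(seq) - 1) * tables.water_mass


def net_charge(seq: str, tables: PhysicoChemicalTables, ph: float) -> float:
    """Modeled net charge at a given pH (Henderson-Hasselbalch terms over the
    termini and ionizable side chains). Strictly decreasing in pH."""
    _check_nonempty(seq)
    pka = tables.pka
    counts = Counter(seq)

    def pos(pk: float, n: float) -> float:
        return n / (1.0 + 10.0 ** (ph - pk))

    def neg(pk: float, n: float) -> float:
        return n / (1.0 + 10.0 ** (pk - ph))

    charge = pos(pka.nterm_by_residue.get(seq[0], pka.nterm), 1.0)
    charge -= neg(pka.cterm_by_residue.get(seq[-1], pka.cterm), 1.0)
    for r in pka.POSITIVE:
        charge += pos(pka.side_chain[r], counts.get(r, 0))
    for r in pka.NEGATIVE:
        charge -= neg(pka.side_chain[r], counts.get(r, 0))
    return charge


def theoretical_pi(
    seq: str, tables: PhysicoChemicalTables, tol: float = 1e-4
) -> float:
    """pH at which the modeled net charge is zero, by bisection on [0, 14]."""
    _check_nonempty(seq)
    lo, hi = 0.0, 14.0
    # net_charge is strictly decreasing; charge(0) > 0 > charge(14) for any
    # peptide with free termini.
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, tables, mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def charge(seq: str, tables: PhysicoChemicalTables) -> float:
    """Summed per-residue charge (K,R +1; D,E -1; H +0.5 by default)."""
    _check_nonempty(seq)
    return sum(tables.residue_charge[r] for r in seq)


def gravy(seq: str, tables: PhysicoChemicalTables) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value."""
    _check_nonempty(seq)
    return sum(tables.kyte_doolittle[r] for r in seq) / len(seq)


def aliphatic_index(seq: str) -> float:
    """X_Ala + 2.9*X_Val + 3.9*(X_Ile + X_Leu) over mole percents."""
    mp = mole_percent(seq)
    return mp["A"] + 2.9 * mp["V"] + 3.9 * (mp["I"] + mp["L"])


def instability_index(seq: str, tables: PhysicoChemicalTables) -> float:
    """(10/L) * sum of dipeptide instability weights over adjacent pairs."""
    if len(seq) < 2:
        raise ValueError("instability index requires length >= 2")
    total = sum(tables.diwv[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 * total / len(seq)


def atom_counts(seq: str, tables: PhysicoChemicalTables) -> Dict[str, int]:
    """Counts of C, H, N, O, S atoms plus the total, from free amino acid
    formulas minus one water (2 H, 1 O) per peptide bond."""
    _check_nonempty(seq)
    sums = [0, 0, 0, 0, 0]
    for r in seq:
        for i, n in enumerate(tables.elemental[r]):
            sums[i] += n
    bonds = len(seq) - 1
    for i, n in enumerate(tables.water_atoms):
        sums[i] -= bonds * n
    out = dict(zip(("C", "H", "N", "O", "S"), sums))
    out["total"] = sum(sums)
    return out


def extinction_coefficients(seq: str) -> Tuple[float, float]:
    """(reduced, cystine-bridged) molar extinction at 280 nm:
    ``5500*nW + 1490*nY`` and the same plus ``125`` per cystine pair."""
    _check_nonempty(seq)
    counts = Counter(seq)
    reduced = 5500.0 * counts.get("W", 0) + 1490.0 * counts.get("Y", 0)
    return reduced, reduced + 125.0 * (counts.get("C", 0) // 2)


def property_class_composition(
    seq: str, tables: PhysicoChemicalTables
) -> Dict[str, Tuple[int, float]]:
    """Count and mole percent of residues in each of the nine property
    classes (tiny, small, aliphatic, aromatic, non-polar, polar, charged,
    basic, acidic)."""
    _check_nonempty(seq)
    counts = Counter(seq)
    length = len(seq)
    out = {}
    for name, members in tables.property_classes.items():
        n = sum(counts.get(r, 0) for r in members)
        out[name] = (n, 100.0 * n / length)
    return out


def charged_residue_counts(seq: str) -> Tuple[int, int]:
    """(negative, positive): counts of D+E and of R+K."""
    _check_nonempty(seq)
    counts = Counter(seq)
    negative = counts.get("D", 0) + counts.get("E", 0)
    positive = counts.get("R", 0) + counts.get("K", 0)
    return negative, positive


def extract_features(
    record: Union[ProteinRecord, str],
    schema: FeatureSchema = None,
    tables: PhysicoChemicalTables = None,
) -> Dict[str, float]:
    """Compute every feature named by the schema for one record.

    Deterministic for a given schema/tables version; shared quantities are
    computed once. Accepts a bare residue string for convenience.
    """
    if schema is None:
        schema = load_schema()
    if tables is None:
        tables = load_tables()
    seq = record.residues if isinstance(record, ProteinRecord) else record
    _check_nonempty(seq)

    mp = mole_percent(seq)
    dh = dayhoffstat(seq, tables)
    classes = property_class_composition(seq, tables)
    atoms = atom_counts(seq, tables)
    negative, positive = charged_residue_counts(seq)
    _, ext_cystine = extinction_coefficients(seq)

    values: Dict[str, float] = {}
    for name in schema.names:
        if name.startswith("mole_percent_"):
            values[name] = mp[name[-1]]
        elif name.startswith("dayhoff_stat_"):
            values[name] = dh[name[-1]]
        elif name.startswith("class_mole_percent_"):
            values[name] = classes[name[len("class_mole_percent_"):]][1]
        elif name.startswith("class_count_"):
            values[name] = float(classes[name[len("class_count_"):]][0])
        elif name.startswith("atoms_"):
            values[name] = float(atoms[name[-1]])
        elif name == "length":
            values[name] = float(len(seq))
        elif name == "molecular_weight":
            values[name] = molecular_weight(seq, tables)
        elif name == "charge":
            values[name] = charge(seq, tables)
        elif name == "theoretical_pi":
            values[name] = theoretical_pi(seq, tables)
        elif name == "negative_residue_count":
            values[name] = float(negative)
        elif name == "positive_residue_count":
            values[name] = float(positive)
        elif name == "gravy":
            values[name] = gravy(seq, tables)
        elif name == "aliphatic_index":
            values[name] = aliphatic_index(seq)
        elif name == "instability_index":
            values[name] = instability_index(seq, tables)
        elif name == "extinction_coefficient_cystine":
            values[name] = ext_cystine
        else:
            raise KeyError(f"schema names unknown feature {name!r}")
        if not math.isfinite(values[name]):
            raise ValueError(f"non-finite value for feature {name!r}")
    return values


def extract_table(
    records: Sequence[ProteinRecord],
    schema: FeatureSchema = None,
    tables: PhysicoChemicalTables = None,
) -> pd.DataFrame:
    """One row per record (indexed by id), columns in schema order."""
    if not records:
        raise ValueError("no records to featurize")
    if schema is None:
        schema = load_schema()
    if tables is None:
        tables = load_tables()
    rows = [extract_features(rec, schema, tables) for rec in records]
    frame = pd.DataFrame(rows, index=[rec.id for rec in records])
    frame = frame[list(schema.names)]
    frame.index.name = "id"
    frame.attrs["schema_version"] = schema.version
    return frame


def write_table(frame: pd.DataFrame, path) -> None:
    """Write a feature table as TSV at 10 significant digits."""
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="id")
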