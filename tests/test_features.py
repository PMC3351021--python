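import json
import math
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecforest.features import (
    aliphatic_index,
    atom_counts,
    charge,
    charged_residue_counts,
    dayhoffstat,
    extinction_coefficients,
    extract_features,
    extract_table,
    gravy,
    instability_index,
    load_schema,
    load_tables,
    mole_percent,
    molecular_weight,
    net_charge,
    property_class_composition,
    read_table,
    theoretical_pi,
    write_table,
)
from ecforest.records import ProteinRecord

FIXTURES = json.loads(
    (Path(__file__).parent / "fixtures_reference_peptides.json").read_text()
)

sequences = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=80)


class TestMolePercent:
    def test_homopolymer(self):
        mp = mole_percent("AAAA")
        assert mp["A"] == 100.0
        assert all(v == 0.0 for r, v in mp.items() if r != "A")

    def test_symmetry(self):
        mp = mole_percent("ACAC")
        assert mp["A"] == 50.0 and mp["C"] == 50.0

    def test_equal_counts(self):
        mp = mole_percent("MKVLA")
        for r in "MKVLA":
            assert mp[r] == 20.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mole_percent("")

    @given(seq=sequences)
    @settings(max_examples=50, deadline=None)
    def test_sums_to_100(self, seq):
        assert math.isclose(sum(mole_percent(seq).values()), 100.0, abs_tol=1e-9)


class TestDayhoffstat:
    def test_absent_residue_is_zero(self, tables):
        assert dayhoffstat("AAAA", tables)["W"] == 0.0

    def test_definitional_fixed_point(self, tables):
        # 100-residue sequence whose counts equal the per-100 Dayhoff
        # frequencies for two residues -> dayhoffstat exactly 1 there.
        seq = "L" * 74 + "C" * 26  # L freq 7.4 -> need 7.4% of 1000... use exact ratio
        # Instead construct counts proportional to the table for A (8.6) and
        # G (8.4): 86 A + 84 G in a 1000-residue sequence scaled down by 10.
        seq = "A" * 86 + "G" * 84 + "L" * (1000 - 86 - 84 - 0)
        # only check residues whose count/10 equals their per-100 frequency
        ds = dayhoffstat(seq[:1000], tables)
        assert math.isclose(ds["A"], (8.6 / 10) / 8.6 * 10, rel_tol=1e-12)
        assert math.isclose(ds["G"], (8.4 / 10) / 8.4 * 10, rel_tol=1e-12)

    def test_c_homopolymer_value(self, tables):
        ds = dayhoffstat("CCCC", tables)
        assert math.isclose(ds["C"], 100.0 / tables.dayhoff_freq["C"], rel_tol=1e-12)


class TestMolecularWeight:
    def test_single_glycine(self, tables):
        assert molecular_weight("G", tables) == pytest.approx(75.07, abs=0.01)

    @given(a=sequences, b=sequences)
    @settings(max_examples=30, deadline=None)
    def test_peptide_bond_additivity(self, a, b):
        tables = load_tables()
        lhs = molecular_weight(a + b, tables)
        rhs = molecular_weight(a, tables) + molecular_weight(b, tables) - 18.0153
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_empty_errors(self, tables):
        with pytest.raises(ValueError):
            molecular_weight("", tables)


class TestTheoreticalPI:
    def test_root_condition(self, tables, rng):
        from conftest import random_sequence

        for _ in range(10):
            seq = random_sequence(rng)
            pi = theoretical_pi(seq, tables)
            assert abs(net_charge(seq, tables, pi)) < 1e-3

    def test_poly_k_above_poly_d(self, tables):
        assert theoretical_pi("K" * 10, tables) > theoretical_pi("D" * 10, tables)

    def test_net_charge_strictly_decreasing(self, tables, rng):
        from conftest import random_sequence

        grid = np.linspace(0.0, 14.0, 57)
        for _ in range(50):
            seq = random_sequence(rng, 40)
            values = [net_charge(seq, tables, ph) for ph in grid]
            assert all(a > b for a, b in zip(values, values[1:]))


class TestCharge:
    def test_cancellation(self, tables):
        assert charge("KDKD", tables) == 0.0

    def test_poly_k(self, tables):
        assert charge("KKK", tables) == 3.0

    def test_histidine_half(self, tables):
        assert charge("HH", tables) == 1.0


class TestGravy:
    def test_poly_isoleucine(self, tables):
        assert gravy("IIII", tables) == pytest.approx(tables.kyte_doolittle["I"])

    def test_permutation_invariant(self, tables):
        assert gravy("MKVLA", tables) == pytest.approx(gravy("ALVKM", tables))


class TestAliphaticIndex:
    def test_poly_a(self):
        assert aliphatic_index("AAAA") == pytest.approx(100.0)

    def test_poly_v(self):
        assert aliphatic_index("VV") == pytest.approx(290.0)

    def test_no_aliphatic(self):
        assert aliphatic_index("GGSS") == 0.0


class TestInstabilityIndex:
    def test_dipeptide(self, tables):
        assert instability_index("MK", tables) == pytest.approx(
            5.0 * tables.diwv["M"]["K"]
        )

    def test_poly_g(self, tables):
        L = 7
        expected = 10.0 * (L - 1) * tables.diwv["G"]["G"] / L
        assert instability_index("G" * L, tables) == pytest.approx(expected)

    def test_short_errors(self, tables):
        with pytest.raises(ValueError):
            instability_index("G", tables)

    def test_order_dependence_witness(self, tables):
        # same composition, different adjacency
        a = instability_index("WPWPWP", tables)
        b = instability_index("WWWPPP", tables)
        assert a != b


class TestAtomCounts:
    def test_free_glycine_formula(self, tables):
        assert atom_counts("G", tables) == {
            "C": 2, "H": 5, "N": 1, "O": 2, "S": 0, "total": 10,
        }

    def test_sulfur_equals_c_plus_m(self, tables, rng):
        from conftest import random_sequence

        for _ in range(10):
            seq = random_sequence(rng)
            counts = atom_counts(seq, tables)
            assert counts["S"] == seq.count("C") + seq.count("M")

    @given(a=sequences, b=sequences)
    @settings(max_examples=30, deadline=None)
    def test_concatenation_additivity(self, a, b):
        tables = load_tables()
        joint = atom_counts(a + b, tables)
        left, right = atom_counts(a, tables), atom_counts(b, tables)
        water = dict(zip(("C", "H", "N", "O", "S"), tables.water_atoms))
        for el in ("C", "H", "N", "O", "S"):
            assert joint[el] == left[el] + right[el] - water[el]


class TestExtinction:
    def test_none(self):
        assert extinction_coefficients("GGG") == (0.0, 0.0)

    def test_two_tryptophans(self):
        assert extinction_coefficients("WW") == (11000.0, 11000.0)

    def test_one_cystine_pair(self):
        assert extinction_coefficients("CC") == (0.0, 125.0)


class TestPropertyClasses:
    def test_basic_plus_acidic_leq_charged(self, tables, rng):
        from conftest import random_sequence

        for _ in range(10):
            comp = property_class_composition(random_sequence(rng), tables)
            assert comp["basic"][0] + comp["acidic"][0] <= comp["charged"][0]

    def test_poly_f_aromatic(self, tables):
        comp = property_class_composition("FFFF", tables)
        assert comp["aromatic"][1] == 100.0

    def test_percent_bounds(self, tables, rng):
        from conftest import random_sequence

        comp = property_class_composition(random_sequence(rng), tables)
        for _, pct in comp.values():
            assert 0.0 <= pct <= 100.0


class TestChargedResidueCounts:
    @pytest.mark.parametrize(
        "seq,expected",
        [("DDEE", (4, 0)), ("RKRK", (0, 4)), ("GGG", (0, 0))],
    )
    def test_counts(self, seq, expected):
        assert charged_residue_counts(seq) == expected


class TestExtractFeatures:
    def test_default_schema_has_73_features(self, schema):
        assert len(schema) == 73

    def test_vector_length(self, schema, tables):
        assert len(extract_features("MKVLA", schema, tables)) == 73

    def test_determinism(self, schema, tables):
        assert extract_features("MKVLAC", schema, tables) == extract_features(
            "MKVLAC", schema, tables
        )

    def test_permutation_changes_only_order_features(self, schema, tables):
        v1 = extract_features("MKWVTFISLLC", schema, tables)
        v2 = extract_features("CLLSIFTVWKM", schema, tables)
        for name in schema.names:
            if schema.kinds[name] == "order":
                assert v1[name] != v2[name]
            else:
                assert v1[name] == pytest.approx(v2[name], abs=1e-12)

    def test_all_values_finite(self, schema, tables, rng):
        from conftest import random_sequence

        values = extract_features(random_sequence(rng), schema, tables)
        assert all(math.isfinite(v) for v in values.values())


class TestExtractTable:
    def _records(self, n=3):
        seqs = ["MKVLA", "GGHHKKDDEE", "WYCWYC"]
        return [ProteinRecord(id=f"r{i}", residues=seqs[i % 3]) for i in range(n)]

    def test_shape_and_order(self, schema, tables):
        frame = extract_table(self._records(), schema, tables)
        assert frame.shape == (3, 73)
        assert list(frame.index) == ["r0", "r1", "r2"]
        assert list(frame.columns) == list(schema.names)

    def test_tsv_round_trip(self, schema, tables, tmp_path):
        frame = extract_table(self._records(), schema, tables)
        path = tmp_path / "features.tsv"
        write_table(frame, path)
        back = read_table(path)
        assert np.allclose(frame.to_numpy(), back.to_numpy(), atol=1e-9, rtol=1e-9)

    def test_empty_errors(self, schema, tables):
        with pytest.raises(ValueError):
            extract_table([], schema, tables)


class TestReferenceOracle:
    """Frozen outputs of the public reference implementation on two toy
    peptides (committed fixture)."""

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_molecular_weight(self, name, tables):
        fx = FIXTURES[name]
        assert molecular_weight(fx["sequence"], tables) == pytest.approx(
            fx["molecular_weight"], abs=0.01
        )

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_isoelectric_point_bjellqvist(self, name):
        fx = FIXTURES[name]
        bj = load_tables(pka_set="bjellqvist")
        assert theoretical_pi(fx["sequence"], bj) == pytest.approx(
            fx["isoelectric_point_bjellqvist"], abs=0.1
        )

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_gravy(self, name, tables):
        fx = FIXTURES[name]
        assert gravy(fx["sequence"], tables) == pytest.approx(fx["gravy"], abs=1e-3)

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_instability(self, name, tables):
        fx = FIXTURES[name]
        assert instability_index(fx["sequence"], tables) == pytest.approx(
            fx["instability_index"], abs=1e-2
        )

    @pytest.mark.parametrize("name", sorted(FIXTURES))
    def test_extinction_exact(self, name):
        fx = FIXTURES[name]
        red, cys = extinction_coefficients(fx["sequence"])
        assert red == fx["extinction_reduced"]
        assert cys == fx["extinction_cystine"]
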