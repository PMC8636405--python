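import itertools

import pytest
from rdkit import Chem

from cliffpix.curation import canonicalize_smiles
from cliffpix.errors import DataError
from cliffpix.mmp import (
    Fragmentation,
    build_index,
    enumerate_fragmentations,
    enumerate_mmps,
    enumerate_mmps_from_records,
    size_filter,
)
from conftest import make_compound


# --- independent brute-force oracle -------------------------------------
def _oracle_cuts(smiles):
    """All (core, substituent) decompositions of one molecule, found by
    cutting every acyclic single bond between heavy atoms directly."""
    mol = Chem.MolFromSmiles(smiles)
    cuts = set()
    for bond in mol.GetBonds():
        if bond.IsInRing() or bond.GetBondType() != Chem.BondType.SINGLE:
            continue
        if bond.GetBeginAtom().GetAtomicNum() < 2 or bond.GetEndAtom().GetAtomicNum() < 2:
            continue
        pieces = Chem.GetMolFrags(
            Chem.FragmentOnBonds(mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)]),
            asMols=True,
        )
        frags = []
        for p in pieces:
            frags.append(
                (Chem.MolToSmiles(p), sum(a.GetAtomicNum() > 1 for a in p.GetAtoms()))
            )
        # both orientations: either piece may act as the core
        for core, sub in (frags, frags[::-1]):
            cuts.add((core[0], core[1], sub[0], sub[1]))
    return cuts


def brute_force_mmps(records):
    """All size-admissible single-cut MMPs by direct pairwise comparison,
    reduced per pair to the largest shared core."""
    out = {}
    for ra, rb in itertools.combinations(records, 2):
        shared = []
        cuts_a, cuts_b = _oracle_cuts(ra.smiles), _oracle_cuts(rb.smiles)
        for core_a, core_ha, sub_a, sub_a_ha in cuts_a:
            for core_b, _, sub_b, sub_b_ha in cuts_b:
                if core_a != core_b or sub_a == sub_b:
                    continue
                if sub_a_ha > 13 or sub_b_ha > 13:
                    continue
                if core_ha < 2 * max(sub_a_ha, sub_b_ha):
                    continue
                if abs(sub_a_ha - sub_b_ha) > 8:
                    continue
                shared.append((core_ha, core_a, sub_a, sub_b))
        if shared:
            core_ha, core, sub_a, sub_b = min(shared, key=lambda s: (-s[0], s[1]))
            key = frozenset((ra.compound_id, rb.compound_id))
            out[key] = (core, frozenset((sub_a, sub_b)))
    return out


def engine_mmps(records):
    return {
        m.pair_key: (m.core_key, frozenset((m.substituent_a, m.substituent_b)))
        for m in enumerate_mmps_from_records(records)
    }


# --- fragmentation -------------------------------------------------------
class TestFragmentation:
    def test_benzene_has_no_cuttable_bond(self):
        assert enumerate_fragmentations(make_compound("b", "c1ccccc1", 6.0)) == []

    def test_methane_has_no_heavy_heavy_bond(self):
        assert enumerate_fragmentations(make_compound("m", "C", 6.0)) == []

    def test_ethylbenzene_has_two_cuts(self):
        frags = enumerate_fragmentations(make_compound("e", "CCc1ccccc1", 6.0))
        assert len(frags) == 2
        subs = sorted(f.substituent_key for f in frags)
        assert subs == ["*C", "*CC"]  # methyl off the ethyl; ethyl off the ring

    def test_amide_bond_is_cut_but_ring_bonds_are_not(self):
        frags = enumerate_fragmentations(make_compound("a", "CC(=O)Nc1ccccc1", 7.0))
        # cuttable: C-C(=O) is part of... C-C single, C(=O)-N, N-ring: 3 cuts
        assert len(frags) == 3

    @pytest.mark.parametrize(
        "smiles", ["CCc1ccccc1", "CC(=O)Nc1ccc(F)cc1", "OCCN1CCCC1", "CC(C)Cc1ccc(C)cc1C(C)C"]
    )
    def test_atom_conservation(self, smiles):
        rec = make_compound("x", smiles, 6.0)
        for f in enumerate_fragmentations(rec):
            assert f.core_heavy_atoms + f.substituent_heavy_atoms == rec.heavy_atom_count
            assert f.core_key.count("*") == 1
            assert f.substituent_key.count("*") == 1

    def test_unparsable_structure_raises(self):
        from cliffpix.curation import CompoundRecord

        bad = CompoundRecord("z", "", 6.0, 1)
        object.__setattr__(bad, "smiles", "not(smiles")
        with pytest.raises(DataError):
            enumerate_fragmentations(bad)


# --- size filter ----------------------------------------------------------
class TestSizeFilter:
    @pytest.mark.parametrize(
        "core, sa, sb, expected",
        [
            (26, 13, 13, True),  # substituent cap boundary: 13 atoms allowed
            (28, 14, 5, False),  # one substituent exceeds the 13-atom cap
            (30, 10, 1, False),  # substituent difference 9 exceeds 8
            (30, 10, 2, True),  # difference exactly 8 allowed
            (19, 10, 3, False),  # core below twice the larger substituent
            (20, 10, 3, True),  # core exactly twice the larger substituent
        ],
    )
    def test_printed_restrictions(self, core, sa, sb, expected):
        assert size_filter(core, sa, sb) is expected

    def test_shrinking_a_substituent_only_fails_via_pair_difference(self):
        # monotone except through the between-substituent difference rule
        for sa in range(13, 0, -1):
            if size_filter(26, sa, 9) != (abs(sa - 9) <= 8):
                assert abs(sa - 9) > 8


# --- index and enumeration -------------------------------------------------
class TestIndexAndEnumeration:
    def test_shared_core_grouped(self):
        f1 = Fragmentation("a", "*c1ccccc1", "*C", 6, 1)
        f2 = Fragmentation("b", "*c1ccccc1", "*CC", 6, 2)
        index = build_index([f1, f2])
        assert set(index) == {"*c1ccccc1"}
        assert len(index["*c1ccccc1"]) == 2

    def test_empty_input_empty_table(self):
        assert build_index([]) == {}

    def test_methyl_ethyl_pair(self):
        # shared phenyl-amide core, methyl vs ethyl exchange
        records = [
            make_compound("a", "CC(=O)Nc1ccccc1C", 6.0),
            make_compound("b", "CC(=O)Nc1ccccc1CC", 7.0),
        ]
        mmps = enumerate_mmps_from_records(records)
        assert len(mmps) == 1
        m = mmps[0]
        assert m.compound_a.compound_id == "b"  # more potent listed first
        assert frozenset((m.substituent_a, m.substituent_b)) == frozenset(("*CC", "*C"))
        assert m.delta_pki == pytest.approx(1.0)

    def test_same_substituent_makes_no_pair(self):
        f1 = Fragmentation("a", "*c1ccccc1CCCCCC", "*C", 12, 1)
        f2 = Fragmentation("b", "*c1ccccc1CCCCCC", "*C", 12, 1)
        index = build_index([f1, f2])
        recs = {
            "a": make_compound("a", "Cc1ccccc1CCCCCC", 6.0),
            "b": make_compound("b", "Cc1ccccc1CCCCCC", 6.0),
        }
        assert enumerate_mmps(index, recs) == []

    def test_order_invariance(self, toy_series):
        forward = engine_mmps(toy_series)
        backward = engine_mmps(list(reversed(toy_series)))
        assert forward == backward

    @pytest.mark.parametrize(
        "series",
        [
            # toluene-family analogs
            ["Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1", "OCc1ccccc1"],
            # para-substituted anilides
            [
                "CC(=O)Nc1ccc(C)cc1",
                "CC(=O)Nc1ccc(CC)cc1",
                "CC(=O)Nc1ccc(O)cc1",
                "CC(=O)Nc1ccc(Cl)cc1",
                "CC(=O)Nc1ccc(F)cc1",
            ],
            # pyridine ethers
            ["COc1ccncc1", "CCOc1ccncc1", "CC(C)Oc1ccncc1", "OCCOc1ccncc1"],
            # piperidine amides with varied tails
            [
                "O=C(N1CCCCC1)c1ccccc1",
                "O=C(N1CCCCC1)c1ccccc1C",
                "O=C(N1CCCCC1)c1ccccc1F",
                "O=C(N1CCCCC1)c1ccccc1Cl",
            ],
            # mixed set with multi-site analogs and a non-analog
            [
                "Cc1ccc(CN2CCOCC2)cc1",
                "CCc1ccc(CN2CCOCC2)cc1",
                "Clc1ccc(CN2CCOCC2)cc1",
                "c1ccc2ccccc2c1",
                "OCc1ccc(CN2CCOCC2)cc1",
            ],
        ],
        ids=["toluenes", "anilides", "pyridines", "piperidines", "mixed"],
    )
    def test_matches_brute_force_oracle(self, series):
        records = [
            make_compound(f"c{i}", smi, 5.0 + 0.3 * i) for i, smi in enumerate(series)
        ]
        assert engine_mmps(records) == brute_force_mmps(records)
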