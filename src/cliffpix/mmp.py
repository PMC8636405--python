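"""Matched-molecular-pair (MMP) enumeration via core-indexed fragment tables.

An MMP is a pair of compounds that share a common core and differ only by
one substituent exchange at a single site.  Enumeration follows the
classical index-table scheme: every acyclic single bond between two heavy
atoms of every compound is cut once, the larger fragment is treated as the
core and the smaller as the substituent, and fragmentations are grouped in
a table keyed by the canonical core string.  Any two compounds meeting at
the same core key with different substituents form a candidate MMP.

Transformation size restrictions keep pairs that look like typically
observed structural analogs: a substituent may contain at most 13
non-hydrogen atoms, the core must be at least twice as large as either
substituent, and the two exchanged substituents may differ by at most
eight non-hydrogen atoms.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd
from rdkit import Chem

from .curation import CompoundRecord
from .errors import DataError

logger = logging.getLogger(__name__)

MAX_SUBSTITUENT_ATOMS = 13
CORE_SIZE_FACTOR = 2.0
MAX_SUBSTITUENT_DIFF = 8


@dataclass(frozen=True)
class Fragmentation:
    """One single-cut decomposition of a compound into core + substituent.

    Both fragment strings carry exactly one ``*`` attachment point; the
    core is the larger fragment (by heavy atoms).
    """

    compound_id: str
    core_key: str
    substituent_key: str
    core_heavy_atoms: int
    substituent_heavy_atoms: int


@dataclass(frozen=True)
class MMP:
    """An ordered matched molecular pair; ``compound_a`` is the more potent."""

    compound_a: CompoundRecord
    compound_b: CompoundRecord
    core_key: str
    substituent_a: str
    substituent_b: str
    delta_pki: float

    @property
    def mmp_id(self) -> str:
        return f"{self.compound_a.compound_id}__{self.compound_b.compound_id}"

    @property
    def pair_key(self) -> frozenset:
        return frozenset((self.compound_a.compound_id, self.compound_b.compound_id))


def _heavy_atoms(mol) -> int:
    # dummy (*) atoms have atomic number 0 and must not be counted
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() > 1)


def single_cut_fragments(mol) -> list[tuple[str, int, str, int]]:
    """All single cuts of acyclic single bonds between heavy atoms.

    Returns ``(core_smiles, core_ha, sub_smiles, sub_ha)`` tuples with the
    larger fragment as core (ties broken toward the lexicographically
    smaller canonical SMILES).  Attachment points appear as ``*`` atoms.
    Duplicate decompositions from symmetric cuts are collapsed.
    """
    out: set[tuple[str, int, str, int]] = set()
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        if bond.GetBeginAtom().GetAtomicNum() <= 1 or bond.GetEndAtom().GetAtomicNum() <= 1:
            continue
        frag_mol = Chem.FragmentOnBonds(
            mol, [bond.GetIdx()], addDummies=True, dummyLabels=[(0, 0)]
        )
        pieces = Chem.GetMolFrags(frag_mol, asMols=True, sanitizeFrags=False)
        if len(pieces) != 2:  # pragma: no cover - single acyclic cut always splits in two
            continue
        keyed = []
        for piece in pieces:
            Chem.SanitizeMol(piece)
            keyed.append((Chem.MolToSmiles(piece), _heavy_atoms(piece)))
        (s0, h0), (s1, h1) = keyed
        if (h0, s1) >= (h1, s0):  # larger fragment is the core; tie -> smaller SMILES
            core, sub = (s0, h0), (s1, h1)
        else:
            core, sub = (s1, h1), (s0, h0)
        out.add((core[0], core[1], sub[0], sub[1]))
    return sorted(out)


def enumerate_fragmentations(compound: CompoundRecord) -> list[Fragmentation]:
    """Every single-cut fragmentation of one compound."""
    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise DataError(f"{compound.compound_id}: unparsable SMILES {compound.smiles!r}")
    frags = []
    for core_s, core_ha, sub_s, sub_ha in single_cut_fragments(mol):
        assert core_ha + sub_ha == compound.heavy_atom_count, (
            f"{compound.compound_id}: fragment atom counts do not sum to parent"
        )
        frags.append(Fragmentation(compound.compound_id, core_s, sub_s, core_ha, sub_ha))
    return frags


def size_filter(
    core_ha: int,
    sub_a_ha: int,
    sub_b_ha: int,
    max_sub_atoms: int = MAX_SUBSTITUENT_ATOMS,
    core_factor: float = CORE_SIZE_FACTOR,
    max_sub_diff: int = MAX_SUBSTITUENT_DIFF,
) -> bool:
    """Transformation size restrictions for one candidate MMP."""
    return (
        sub_a_ha <= max_sub_atoms
        and sub_b_ha <= max_sub_atoms
        and core_ha >= core_factor * max(sub_a_ha, sub_b_ha)
        and abs(sub_a_ha - sub_b_ha) <= max_sub_diff
    )


def build_index(fragmentations) -> dict[str, list[Fragmentation]]:
    """Group fragmentations by canonical core key."""
    index: dict[str, list[Fragmentation]] = defaultdict(list)
    for frag in fragmentations:
        index[frag.core_key].append(frag)
    return dict(index)


def enumerate_mmps(
    index: dict[str, list[Fragmentation]],
    compounds,
    max_sub_atoms: int = MAX_SUBSTITUENT_ATOMS,
    core_factor: float = CORE_SIZE_FACTOR,
    max_sub_diff: int = MAX_SUBSTITUENT_DIFF,
    keep_all_cores: bool = False,
) -> list[MMP]:
    """All size-admissible MMPs from a core index.

    ``compounds`` maps compound ids to :class:`CompoundRecord`.  A pair
    matching on several cores is reduced to one MMP through the largest
    core (ties broken by the lexicographically smallest core key) unless
    ``keep_all_cores`` is set.  Within a pair, ``compound_a`` is the more
    potent compound (ties broken by compound id).
    """
    by_id = dict(compounds) if not hasattr(compounds, "keys") else dict(compounds)
    candidates: dict[frozenset, list[tuple[int, str, Fragmentation, Fragmentation]]] = (
        defaultdict(list)
    )
    for core_key, entries in index.items():
        if len(entries) < 2:
            continue
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                fa, fb = entries[i], entries[j]
                if fa.compound_id == fb.compound_id:
                    continue
                if fa.substituent_key == fb.substituent_key:
                    continue
                if not size_filter(
                    fa.core_heavy_atoms,
                    fa.substituent_heavy_atoms,
                    fb.substituent_heavy_atoms,
                    max_sub_atoms=max_sub_atoms,
                    core_factor=core_factor,
                    max_sub_diff=max_sub_diff,
                ):
                    continue
                pair = frozenset((fa.compound_id, fb.compound_id))
                candidates[pair].append((fa.core_heavy_atoms, core_key, fa, fb))

    mmps: list[MMP] = []
    for pair, cores in sorted(candidates.items(), key=lambda kv: sorted(kv[0])):
        if keep_all_cores:
            chosen = sorted(cores, key=lambda c: (-c[0], c[1]))
        else:
            chosen = [min(cores, key=lambda c: (-c[0], c[1]))]
        for _, core_key, fa, fb in chosen:
            rec_a, rec_b = by_id[fa.compound_id], by_id[fb.compound_id]
            sub_a, sub_b = fa.substituent_key, fb.substituent_key
            if (rec_b.pki, rec_a.compound_id) > (rec_a.pki, rec_b.compound_id):
                rec_a, rec_b = rec_b, rec_a
                sub_a, sub_b = sub_b, sub_a
            mmps.append(
                MMP(
                    compound_a=rec_a,
                    compound_b=rec_b,
                    core_key=core_key,
                    substituent_a=sub_a,
                    substituent_b=sub_b,
                    delta_pki=abs(rec_a.pki - rec_b.pki),
                )
            )
    return mmps


def enumerate_mmps_from_records(records, **kwargs) -> list[MMP]:
    """Convenience path: fragment, index and pair a curated compound list."""
    frags = []
    for rec in records:
        frags.extend(enumerate_fragmentations(rec))
    index = build_index(frags)
    return enumerate_mmps(index, {r.compound_id: r for r in records}, **kwargs)


def mmps_to_frame(mmps) -> pd.DataFrame:
    """MMP list as a flat table (one row per pair)."""
    return pd.DataFrame(
        {
            "id_a": [m.compound_a.compound_id for m in mmps],
            "id_b": [m.compound_b.compound_id for m in mmps],
            "core_smiles": [m.core_key for m in mmps],
            "sub_a_smiles": [m.substituent_a for m in mmps],
            "sub_b_smiles": [m.substituent_b for m in mmps],
            "pki_a": [m.compound_a.pki for m in mmps],
            "pki_b": [m.compound_b.pki for m in mmps],
            "delta_pki": [m.delta_pki for m in mmps],
        }
    )
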