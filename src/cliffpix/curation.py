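"""Curation of raw compound potency tables.

Activity classes arrive as delimited tables with one row per measurement:
a compound identifier, a SMILES string and a pKi value (the negative
base-10 logarithm of the equilibrium inhibition constant, so one pKi unit
equals one order of magnitude in potency).  Curation reduces these to one
record per compound:

* repeated measurements are averaged on the pKi (log) scale, provided all
  values fall within the same order of magnitude; compounds whose
  measurements spread over more than one log unit are rejected outright;
* SMILES are canonicalized, and for multi-component inputs (salts) only
  the largest covalent component is kept;
* rows with unparsable structures are dropped and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from rdkit import Chem

from .errors import DataError, UsageError

logger = logging.getLogger(__name__)

#: Maximum allowed spread (max - min, in pKi units) among repeated
#: measurements of one compound.  One pKi unit is one order of magnitude.
DEFAULT_MAX_SPREAD = 1.0


@dataclass(frozen=True)
class RawActivityRecord:
    """One compound with all its raw potency measurements."""

    compound_id: str
    smiles: str
    pki_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.pki_values) == 0:
            raise UsageError(f"{self.compound_id}: empty pKi value list")
        for v in self.pki_values:
            if not math.isfinite(v):
                raise DataError(f"{self.compound_id}: non-finite pKi value {v!r}")


@dataclass(frozen=True)
class CompoundRecord:
    """A curated compound: canonical SMILES and a single potency."""

    compound_id: str
    smiles: str
    pki: float
    heavy_atom_count: int

    def __post_init__(self) -> None:
        if not math.isfinite(self.pki):
            raise DataError(f"{self.compound_id}: non-finite curated pKi")
        if self.heavy_atom_count < 1:
            raise DataError(f"{self.compound_id}: no heavy atoms")


def curate_potency(
    values,
    max_spread: float = DEFAULT_MAX_SPREAD,
    strict: bool = True,
    scale: str = "pki",
) -> float | None:
    """Reduce repeated potency measurements to one value, or reject.

    Values are averaged provided they all fall within the same order of
    magnitude (max - min below ``max_spread`` pKi units); otherwise the
    compound is disregarded and ``None`` is returned.

    Parameters
    ----------
    values
        Non-empty sequence of pKi measurements.
    max_spread
        Spread threshold in pKi units (default one order of magnitude).
    strict
        If True (default) a spread exactly equal to ``max_spread``
        rejects; if False it is still accepted.
    scale
        ``"pki"`` (default) averages arithmetically on the log scale;
        ``"ki"`` averages the back-transformed Ki values and returns the
        result on the pKi scale.

    Returns
    -------
    float or None
        The curated pKi, or ``None`` when the compound is rejected.
    """
    values = list(values)
    if not values:
        raise UsageError("curate_potency: empty value list")
    for v in values:
        if not math.isfinite(v):
            raise DataError(f"curate_potency: non-finite value {v!r}")
    spread = max(values) - min(values)
    rejected = spread >= max_spread if strict else spread > max_spread
    if rejected:
        return None
    if scale == "pki":
        mean = sum(values) / len(values)
    elif scale == "ki":
        ki = [10.0 ** (-v) for v in values]
        mean = -math.log10(sum(ki) / len(ki))
    else:
        raise UsageError(f"curate_potency: unknown scale {scale!r}")
    # clamp float round-off so the result stays within the measured range
    return min(max(mean, min(values)), max(values))


def canonicalize_smiles(smiles: str) -> tuple[str, int] | None:
    """Canonical SMILES and heavy-atom count, or None if unparsable.

    Multi-component structures keep only the largest covalent component
    (by heavy-atom count; ties broken by canonical SMILES order).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        frags = sorted(
            frags,
            key=lambda m: (-m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)),
        )
        mol = frags[0]
        logger.warning(
            "multi-component structure %r reduced to largest component", smiles
        )
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy < 1:
        return None
    return Chem.MolToSmiles(mol), n_heavy


def curate_records(
    raw_records,
    max_spread: float = DEFAULT_MAX_SPREAD,
    strict: bool = True,
    scale: str = "pki",
) -> list[CompoundRecord]:
    """Apply structure canonicalization and potency curation to raw records."""
    curated: list[CompoundRecord] = []
    for rec in raw_records:
        canon = canonicalize_smiles(rec.smiles)
        if canon is None:
            logger.warning("dropping %s: unparsable SMILES %r", rec.compound_id, rec.smiles)
            continue
        smiles, n_heavy = canon
        pki = curate_potency(rec.pki_values, max_spread=max_spread, strict=strict, scale=scale)
        if pki is None:
            logger.info(
                "dropping %s: measurement spread exceeds %.2f log units",
                rec.compound_id,
                max_spread,
            )
            continue
        curated.append(CompoundRecord(rec.compound_id, smiles, pki, n_heavy))
    return curated


def load_activity_class(
    path,
    id_col: str = "compound_id",
    smiles_col: str = "smiles",
    pki_col: str = "pki",
    sep: str | None = None,
    max_spread: float = DEFAULT_MAX_SPREAD,
    strict: bool = True,
    scale: str = "pki",
) -> list[CompoundRecord]:
    """Load a delimited activity table and return curated compound records.

    Rows sharing a compound id are merged through :func:`curate_potency`;
    rows with unparsable SMILES are dropped with a warning.  The delimiter
    is sniffed from the file extension unless ``sep`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"activity table not found: {path}")
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        table = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot read activity table {path}: {exc}") from exc
    for col in (id_col, smiles_col, pki_col):
        if col not in table.columns:
            raise DataError(f"{path}: missing column {col!r}")
    table = table.dropna(subset=[id_col, smiles_col, pki_col])
    raw: list[RawActivityRecord] = []
    for cid, group in table.groupby(id_col, sort=True):
        smiles = str(group[smiles_col].iloc[0])
        values = tuple(float(v) for v in group[pki_col])
        try:
            raw.append(RawActivityRecord(str(cid), smiles, values))
        except DataError as exc:
            raise DataError(f"{path}: {exc}") from exc
    records = curate_records(raw, max_spread=max_spread, strict=strict, scale=scale)
    if not records:
        raise DataError(f"{path}: no valid rows after curation")
    return records


def write_curated(records, path) -> None:
    """Write curated records as CSV (compound_id, canonical_smiles, pki)."""
    pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "smiles": [r.smiles for r in records],
            "pki": [r.pki for r in records],
        }
    ).to_csv(path, index=False)
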