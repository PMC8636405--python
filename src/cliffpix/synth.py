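"""Synthetic analog series with planted, image-visible cliff substituents.

The generator emulates the combinatorial make-up of real activity
classes: a handful of shared scaffolds (cores), each decorated at one
position with substituents drawn from a common library.  Potency follows
an additive model,

    pKi(core, substituent) = base(core) + effect(substituent) + noise,

with independent Gaussian measurement noise per compound.  A small subset
of "cliff" substituents carries a large potency effect and a visually
distinctive substructure (an aliphatic diamine ring), so that any pair
exchanging a cliff substituent against an ordinary one crosses the
100-fold potency gap and the discriminative signal is present in the
substituent pixels of the rendered pair image.  Ordinary substituent
effects span well under one log unit, so those pairs stay non-AC.

Cliffs are a small minority of pairs, mirroring the imbalance of real
MMP data sets where cliff pairs are rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .curation import RawActivityRecord
from .dataset import AC_THRESHOLD, NON_AC_THRESHOLD, Label
from .errors import UsageError

ATTACHMENT = "[*:1]"


@dataclass(frozen=True)
class Substituent:
    smiles: str  # carries one [*:1] attachment point
    effect: float  # additive potency contribution, pKi units
    is_cliff: bool = False


@dataclass(frozen=True)
class SeriesSpec:
    """Parameters of one synthetic benchmark series."""

    core_templates: tuple[str, ...]  # scaffolds, one [*:1] each
    base_potencies: tuple[float, ...]  # per-core baseline pKi
    substituents: tuple[Substituent, ...]
    noise_sd: float = 0.1  # measurement noise, pKi units
    target_ac_prevalence: float = 0.10
    seed: int = 0

    @property
    def n_cores(self) -> int:
        return len(self.core_templates)

    def validate(self) -> None:
        if len(self.core_templates) != len(self.base_potencies):
            raise UsageError("one base potency per core template required")
        for smi in self.core_templates:
            if ATTACHMENT not in smi or Chem.MolFromSmiles(smi) is None:
                raise UsageError(f"invalid core template {smi!r}")
        for sub in self.substituents:
            if ATTACHMENT not in sub.smiles or Chem.MolFromSmiles(sub.smiles) is None:
                raise UsageError(f"invalid substituent {sub.smiles!r}")
        effects = [s.effect for s in self.substituents]
        diffs = [abs(a - b) for i, a in enumerate(effects) for b in effects[i + 1 :]]
        if not any(d >= AC_THRESHOLD + 3 * self.noise_sd for d in diffs):
            raise UsageError("no substituent pair achieves a robust cliff gap")
        if not any(d <= NON_AC_THRESHOLD - 3 * self.noise_sd for d in diffs):
            raise UsageError("no substituent pair achieves a robust non-AC gap")


def assemble(core_template: str, substituent: str) -> str | None:
    """Bond a substituent to the core's open position; canonical SMILES."""
    core = Chem.MolFromSmiles(core_template)
    sub = Chem.MolFromSmiles(substituent)
    if core is None or sub is None:
        return None
    try:
        combined = Chem.molzip(Chem.CombineMols(core, sub))
        Chem.SanitizeMol(combined)
    except Exception:
        return None
    return Chem.MolToSmiles(combined)


def compound_id(core_idx: int, sub_idx: int) -> str:
    return f"C{core_idx:02d}S{sub_idx:02d}"


def generate_series(spec: SeriesSpec, seed: int | None = None) -> list[RawActivityRecord]:
    """Full core x substituent grid with additive potencies plus noise."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    records: list[RawActivityRecord] = []
    for ci, (core, base) in enumerate(zip(spec.core_templates, spec.base_potencies)):
        for si, sub in enumerate(spec.substituents):
            smiles = assemble(core, sub.smiles)
            if smiles is None:  # pragma: no cover - library templates all assemble
                import logging

                logging.getLogger(__name__).warning(
                    "skipping invalid assembly core=%r sub=%r", core, sub.smiles
                )
                continue
            noise = rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0
            pki = base + sub.effect + noise
            records.append(RawActivityRecord(compound_id(ci, si), smiles, (float(pki),)))
    return records


def expected_labels(spec: SeriesSpec) -> dict[frozenset, Label]:
    """Analytic pair labels at zero noise, keyed by compound-id pairs.

    Only within-core pairs are labeled; by construction cores are
    structurally unrelated, so cross-core pairs never form MMPs.
    """
    labels: dict[frozenset, Label] = {}
    for ci in range(spec.n_cores):
        for si in range(len(spec.substituents)):
            for sj in range(si + 1, len(spec.substituents)):
                d = abs(spec.substituents[si].effect - spec.substituents[sj].effect)
                if d >= AC_THRESHOLD:
                    lbl = Label.AC
                elif d <= NON_AC_THRESHOLD:
                    lbl = Label.NON_AC
                else:
                    lbl = Label.EXCLUDED
                labels[frozenset((compound_id(ci, si), compound_id(ci, sj)))] = lbl
    return labels


#: Scaffolds of 15-17 heavy atoms, pairwise structurally unrelated so that
#: matched pairs only form within a series.
DEFAULT_CORES = (
    "O=C(Nc1ccccc1)c1ccc([*:1])cc1",
    "c1ccc(-c2nc3ccc([*:1])cc3s2)cc1",
    "CCOc1ccc(C(=O)N2CCC([*:1])CC2)cc1",
    "O=C(Cc1ccccc1)Nc1ccc([*:1])cn1",
)

DEFAULT_BASE_POTENCIES = (6.0, 6.5, 7.0, 7.5)

#: Ordinary substituents span 0.52 pKi units; the single cliff substituent
#: (a piperazine ring, i.e. a cyclic diamine) sits 2.8 units above the
#: weakest, so cliff-vs-ordinary exchanges differ by 2.28-2.80 units.
DEFAULT_SUBSTITUENTS = (
    Substituent("[*:1]C", 0.00),
    Substituent("[*:1]CC", 0.08),
    Substituent("[*:1]CCC", 0.16),
    Substituent("[*:1]C(C)C", 0.24),
    Substituent("[*:1]CCCC", 0.32),
    Substituent("[*:1]OC", 0.12),
    Substituent("[*:1]OCC", 0.20),
    Substituent("[*:1]F", 0.04),
    Substituent("[*:1]Cl", 0.28),
    Substituent("[*:1]Br", 0.36),
    Substituent("[*:1]CO", 0.40),
    Substituent("[*:1]C(C)=O", 0.44),
    Substituent("[*:1]C#N", 0.48),
    Substituent("[*:1]OC(C)C", 0.52),
    Substituent("[*:1]N1CCNCC1", 2.80, is_cliff=True),
)


def default_benchmark_spec(seed: int = 0, noise_sd: float = 0.1) -> SeriesSpec:
    """The packaged benchmark: 4 cores x 15 substituents (~420 MMPs).

    With one cliff substituent per series, cliff pairs make up roughly
    13% of all pairs before exclusion, inside the 5-15% minority range
    the benchmark targets.
    """
    return SeriesSpec(
        core_templates=DEFAULT_CORES,
        base_potencies=DEFAULT_BASE_POTENCIES,
        substituents=DEFAULT_SUBSTITUENTS,
        noise_sd=noise_sd,
        target_ac_prevalence=0.13,
        seed=seed,
    )
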