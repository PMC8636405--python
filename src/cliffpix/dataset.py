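"""Cliff labeling, multiplicity filtering and trial splitting for MMP sets.

An MMP is labeled a cliff (AC) when its two analogs differ by at least
100-fold in potency (delta pKi >= 2.0) and a non-AC when they differ by
at most tenfold (delta pKi <= 1.0).  The open interval between the two
thresholds is excluded from modeling to avoid boundary effects that
depend on the potency difference itself.

To temper structural heterogeneity, MMPs are only retained if their
compounds and core structures occur in multiple MMPs; the criterion is
re-evaluated after removals until a fixed point is reached.  Repeated
trials use per-label stratified random halving with seeds derived
deterministically from a base seed.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .errors import DataError, UsageError
from .mmp import MMP

logger = logging.getLogger(__name__)

AC_THRESHOLD = 2.0
NON_AC_THRESHOLD = 1.0


class Label(str, Enum):
    AC = "AC"
    NON_AC = "NON_AC"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class LabeledMMP:
    mmp: MMP
    label: Label

    @property
    def mmp_id(self) -> str:
        return self.mmp.mmp_id


@dataclass(frozen=True)
class TrialSplit:
    trial_seed: int
    train: tuple[LabeledMMP, ...]
    test: tuple[LabeledMMP, ...]


def label_mmp(
    mmp: MMP,
    ac_threshold: float = AC_THRESHOLD,
    non_ac_threshold: float = NON_AC_THRESHOLD,
) -> LabeledMMP:
    """Assign AC / NON_AC / EXCLUDED from the pair's potency difference."""
    d = mmp.delta_pki
    if d < 0:
        raise UsageError(f"{mmp.mmp_id}: negative delta_pki {d}")
    if d >= ac_threshold:
        label = Label.AC
    elif d <= non_ac_threshold:
        label = Label.NON_AC
    else:
        label = Label.EXCLUDED
    return LabeledMMP(mmp, label)


def label_mmps(mmps, **kwargs) -> list[LabeledMMP]:
    return [label_mmp(m, **kwargs) for m in mmps]


def drop_excluded(labeled) -> list[LabeledMMP]:
    return [lm for lm in labeled if lm.label is not Label.EXCLUDED]


def multiplicity_filter(
    labeled,
    min_count: int = 2,
    iterative: bool = True,
) -> list[LabeledMMP]:
    """Retain MMPs whose compounds and core occur in multiple MMPs.

    Occurrences are counted across all currently retained MMPs (labels
    pooled).  With ``iterative`` (default) the criterion is re-applied
    after each simultaneous removal round until nothing changes, which
    makes the result independent of input order; a single pass is
    available for comparison.
    """
    retained = list(labeled)
    while True:
        compound_counts: Counter = Counter()
        core_counts: Counter = Counter()
        for lm in retained:
            compound_counts[lm.mmp.compound_a.compound_id] += 1
            compound_counts[lm.mmp.compound_b.compound_id] += 1
            core_counts[lm.mmp.core_key] += 1
        keep = [
            lm
            for lm in retained
            if compound_counts[lm.mmp.compound_a.compound_id] >= min_count
            and compound_counts[lm.mmp.compound_b.compound_id] >= min_count
            and core_counts[lm.mmp.core_key] >= min_count
        ]
        changed = len(keep) != len(retained)
        retained = keep
        if not changed or not iterative:
            return retained


def trial_seed(base_seed: int, trial: int) -> int:
    """Deterministic per-trial seed derived from the base seed."""
    ss = np.random.SeedSequence([base_seed, trial])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def make_splits(labeled, n_trials: int, base_seed: int) -> list[TrialSplit]:
    """Stratified random halving, repeated over independent trials.

    Each trial shuffles every label class with its own derived seed and
    puts ceil(n/2) members in the training half, the rest in the test
    half.  EXCLUDED members must have been dropped beforehand.
    """
    labeled = list(labeled)
    if any(lm.label is Label.EXCLUDED for lm in labeled):
        raise UsageError("make_splits: EXCLUDED MMPs must be dropped first")
    by_label: dict[Label, list[LabeledMMP]] = {Label.AC: [], Label.NON_AC: []}
    for lm in labeled:
        by_label[lm.label].append(lm)
    for lbl, members in by_label.items():
        if len(members) < 2:
            raise DataError(
                f"make_splits: label class {lbl.value} has {len(members)} member(s); need >= 2"
            )
    splits = []
    for t in range(n_trials):
        seed = trial_seed(base_seed, t)
        rng = np.random.default_rng(seed)
        train: list[LabeledMMP] = []
        test: list[LabeledMMP] = []
        for lbl in (Label.AC, Label.NON_AC):
            members = by_label[lbl]
            order = rng.permutation(len(members))
            n_train = (len(members) + 1) // 2
            train.extend(members[i] for i in order[:n_train])
            test.extend(members[i] for i in order[n_train:])
        splits.append(TrialSplit(trial_seed=seed, train=tuple(train), test=tuple(test)))
    return splits


def labeled_to_frame(labeled) -> pd.DataFrame:
    from .mmp import mmps_to_frame

    frame = mmps_to_frame([lm.mmp for lm in labeled])
    frame["label"] = [lm.label.value for lm in labeled]
    return frame


def splits_to_json(splits, path) -> None:
    payload = [
        {
            "trial_seed": s.trial_seed,
            "train": [lm.mmp_id for lm in s.train],
            "test": [lm.mmp_id for lm in s.test],
        }
        for s in splits
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
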