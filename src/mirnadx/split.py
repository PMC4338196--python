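"""Stratified random partition into training and test cohorts.

Each clinical group is shuffled independently with a single seeded
generator (samples sorted by ID first, so the split is a pure function of
the ID set and the seed) and cut at floor(n * train_fraction + 0.5).
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np

from .types import ClinicalGroup, CohortSplit, SampleAnnotation, check_unique_sample_ids

logger = logging.getLogger(__name__)


def stratified_split(
    annotations: Sequence[SampleAnnotation],
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    counts_override: Mapping[ClinicalGroup, tuple[int, int]] | None = None,
) -> CohortSplit:
    """Randomly divide samples into training and test cohorts within each
    clinical group.

    ``counts_override`` maps a group to explicit (train, test) sizes,
    replacing the rounding rule for that group — published partitions are
    not always consistent with a single rounding rule.

    A group with fewer than 2 samples cannot populate both cohorts and is
    placed entirely in training, with a warning.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0, 1)")
    check_unique_sample_ids(annotations)
    rng = np.random.default_rng(seed)

    train_ids: list[str] = []
    test_ids: list[str] = []
    per_group: dict[ClinicalGroup, tuple[int, int]] = {}
    for group in ClinicalGroup:
        ids = sorted(a.sample_id for a in annotations if a.group is group)
        n = len(ids)
        if n == 0:
            continue
        if n < 2:
            logger.warning(
                "group %s has %d sample(s); placed entirely in training", group, n
            )
            train_ids.extend(ids)
            per_group[group] = (n, 0)
            continue
        if counts_override and group in counts_override:
            n_train, n_test = counts_override[group]
            if n_train + n_test != n:
                raise ValueError(
                    f"override counts for {group} sum to {n_train + n_test}, "
                    f"but the group has {n} samples"
                )
        else:
            n_train = int(math.floor(n * train_fraction + 0.5))
            n_train = min(max(n_train, 1), n - 1)  # both cohorts non-empty
        shuffled = list(np.array(ids)[rng.permutation(n)])
        train_ids.extend(shuffled[:n_train])
        test_ids.extend(shuffled[n_train:])
        per_group[group] = (n_train, n - n_train)

    return CohortSplit(
        train_ids=train_ids,
        test_ids=test_ids,
        seed=seed,
        per_group_counts=per_group,
    )
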