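"""Stratified random data partitioning and seed derivation.

Two levels of splitting are provided: the discovery/classification split
(the extra partition this method introduces, at discovery fraction ``f``)
and stratified k-folds used for cross-validated evaluation.  Both are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .seq_io import Dataset, NEGATIVE, POSITIVE

DEFAULT_DISCOVERY_FRACTION = 0.10


def spawn_seed(master_seed: int, *key: int) -> int:
    """Derive an independent child seed from a master seed and an index key.

    Uses numpy's SeedSequence so per-run / per-component streams are
    statistically independent and reproducible regardless of execution
    order.  The result fits in 31 bits.
    """
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass(frozen=True)
class SplitSpec:
    """Discovery fraction f in (0, 1) plus the split seed."""

    f: float = DEFAULT_DISCOVERY_FRACTION
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.f < 1.0:
            raise ValueError(f"discovery fraction f must be in (0, 1), got {self.f}")


@dataclass(frozen=True)
class Partition:
    """Disjoint discovery/classification id sets covering the dataset."""

    discovery_ids: tuple[str, ...]
    classification_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.discovery_ids) & set(self.classification_ids):
            raise ValueError("discovery and classification sets overlap")


def _per_class_discovery_count(f: float, n_class: int) -> int:
    # Symmetric deterministic rounding: floor(f*n + 0.5).
    return int(np.floor(f * n_class + 0.5))


def stratified_split(data: Dataset, spec: SplitSpec) -> Partition:
    """Randomly split into discovery and classification sets, stratified by class.

    Per-class discovery counts are ``floor(f * n_class + 0.5)``; a class
    that would contribute zero discovery sequences (or lose its whole
    classification side) is an error asking for a different ``f``.
    Identical (data, spec) inputs yield identical partitions.
    """
    rng = np.random.default_rng(spec.seed)
    discovery: list[str] = []
    classification: list[str] = []
    for label in (POSITIVE, NEGATIVE):
        ids = [s.id for s in data.sequences if s.label == label]
        n = len(ids)
        if n < 2:
            raise ValueError(f"class {label} has {n} sequences; need at least 2 to split")
        n_disc = _per_class_discovery_count(spec.f, n)
        if n_disc == 0:
            raise ValueError(
                f"discovery fraction f={spec.f} gives 0 discovery sequences for a class "
                f"of size {n}; use a larger f"
            )
        if n_disc >= n:
            raise ValueError(
                f"discovery fraction f={spec.f} consumes an entire class of size {n}; "
                f"use a smaller f"
            )
        order = rng.permutation(n)
        discovery.extend(ids[i] for i in order[:n_disc])
        classification.extend(ids[i] for i in order[n_disc:])
    return Partition(tuple(sorted(discovery)), tuple(sorted(classification)))


def stratified_folds(ids: Sequence[str], labels: Sequence[int], k: int,
                     seed: int) -> list[list[str]]:
    """Partition ids into k stratified validation folds.

    Folds are disjoint, cover all ids, and per-fold class counts differ
    by at most 1 from exact proportionality.  A class smaller than k is
    an error (callers may lower k first).
    """
    if k < 2:
        raise ValueError(f"fold count k must be >= 2, got {k}")
    if len(ids) != len(labels):
        raise ValueError("ids and labels must have equal length")
    rng = np.random.default_rng(seed)
    folds: list[list[str]] = [[] for _ in range(k)]
    for label in sorted(set(labels)):
        class_ids = [i for i, lab in zip(ids, labels) if lab == label]
        if len(class_ids) < k:
            raise ValueError(f"class {label} has {len(class_ids)} ids, fewer than k={k} folds")
        order = rng.permutation(len(class_ids))
        for pos, idx in enumerate(order):
            folds[pos % k].append(class_ids[idx])
    return [sorted(fold) for fold in folds]


def write_partition_tsv(path: str | Path, partition: Partition) -> None:
    """Serialize as a two-column TSV (id, set) so runs are auditable."""
    with open(path, "w") as fh:
        fh.write("id\tset\n")
        for sid in partition.discovery_ids:
            fh.write(f"{sid}\tdiscovery\n")
        for sid in partition.classification_ids:
            fh.write(f"{sid}\tclassification\n")


def read_partition_tsv(path: str | Path) -> Partition:
    discovery: list[str] = []
    classification: list[str] = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "id\tset":
            raise ValueError(f"{path}: unexpected partition header {header!r}")
        for line in fh:
            sid, which = line.rstrip("\n").split("\t")
            if which == "discovery":
                discovery.append(sid)
            elif which == "classification":
                classification.append(sid)
            else:
                raise ValueError(f"{path}: unknown set name {which!r}")
    return Partition(tuple(discovery), tuple(classification))
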