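"""Random four-way split design: active training (A), passive training (P),
calibration (C) and validation (V), each holding ≈25% of the records.

Several independent random splits of the same dataset are the raw material
of the self-consistent-model analysis; :func:`split_similarity` quantifies
how much two splits overlap (independent random 25% splits sit near 25%,
comfortably under the 30% design ceiling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "SplitAssignment",
    "make_splits",
    "split_similarity",
    "average_pairwise_similarity",
    "write_splits",
    "read_splits",
    "leakage_report",
]

LABELS = ("A", "P", "C", "V")


@dataclass
class SplitAssignment:
    """A partition of record ids into the four set labels."""

    split_id: int
    assignment: Dict[Hashable, str]

    def __post_init__(self) -> None:
        bad = {l for l in self.assignment.values() if l not in LABELS}
        if bad:
            raise ValueError(f"unknown set labels: {sorted(bad)}")

    def ids(self, label: str) -> List[Hashable]:
        if label not in LABELS:
            raise ValueError(f"unknown label {label!r}")
        return [r for r, l in self.assignment.items() if l == label]

    def record_ids(self) -> List[Hashable]:
        return list(self.assignment)

    def sizes(self) -> Dict[str, int]:
        out = {l: 0 for l in LABELS}
        for l in self.assignment.values():
            out[l] += 1
        return out

    def validate(self, record_ids: Sequence[Hashable]) -> None:
        """Assert the partition invariant against a reference id list."""
        ref = set(record_ids)
        got = set(self.assignment)
        if ref != got:
            raise ValueError(
                f"split {self.split_id} does not partition the record set: "
                f"{len(ref - got)} missing, {len(got - ref)} extraneous"
            )


def make_splits(
    record_ids: Sequence[Hashable], n_splits: int, seed: int
) -> List[SplitAssignment]:
    """Generate ``n_splits`` independent seeded random partitions.

    Each split permutes the ids and chunks the permutation into four
    near-equal sets; the remainder (n mod 4) is distributed round-robin
    over the labels in order A, P, C, V.
    """
    ids = list(record_ids)
    n = len(ids)
    if n < 8:
        raise ValueError("need at least 8 records to populate four sets with >= 2 each")
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if len(set(ids)) != n:
        raise ValueError("record ids must be unique")
    streams = np.random.SeedSequence(seed).spawn(n_splits)
    splits = []
    base, rem = divmod(n, 4)
    sizes = [base + (1 if i < rem else 0) for i in range(4)]
    for sid, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        perm = rng.permutation(n)
        assignment: Dict[Hashable, str] = {}
        pos = 0
        for label, size in zip(LABELS, sizes):
            for j in perm[pos : pos + size]:
                assignment[ids[j]] = label
            pos += size
        splits.append(SplitAssignment(split_id=sid, assignment=assignment))
    return splits


def split_similarity(
    s1: SplitAssignment, s2: SplitAssignment, metric: str = "per_label"
) -> float:
    """Percentage similarity of two splits of the same record set.

    ``per_label`` (default): mean over the four labels of
    ``100 * |set_L(s1) ∩ set_L(s2)| / |set_L(s1)|``.  Identical splits give
    100; independent random 25% splits give ≈25.  ``jaccard`` replaces the
    fraction with the Jaccard index of the two label sets.
    """
    if set(s1.assignment) != set(s2.assignment):
        raise ValueError("splits cover different record sets")
    vals = []
    for label in LABELS:
        a = set(s1.ids(label))
        b = set(s2.ids(label))
        if metric == "per_label":
            vals.append(100.0 * len(a & b) / len(a))
        elif metric == "jaccard":
            vals.append(100.0 * len(a & b) / len(a | b))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return float(np.mean(vals))


def average_pairwise_similarity(
    splits: Sequence[SplitAssignment], metric: str = "per_label"
) -> float:
    """Mean similarity over all unordered pairs of splits."""
    if len(splits) < 2:
        raise ValueError("need at least two splits")
    vals = [
        split_similarity(splits[i], splits[k], metric)
        for i in range(len(splits))
        for k in range(i + 1, len(splits))
    ]
    return float(np.mean(vals))


def write_splits(splits: Sequence[SplitAssignment], path) -> None:
    """Write splits as a TSV with columns record_id, split_id, set_label."""
    rows = [
        (rid, s.split_id, label)
        for s in splits
        for rid, label in s.assignment.items()
    ]
    pd.DataFrame(rows, columns=["record_id", "split_id", "set_label"]).to_csv(
        path, sep="\t", index=False
    )


def read_splits(path) -> List[SplitAssignment]:
    """Read a split file and validate each split's partition invariant."""
    df = pd.read_csv(path, sep="\t", dtype={"record_id": str})
    missing = {"record_id", "split_id", "set_label"} - set(df.columns)
    if missing:
        raise ValueError(f"split file lacks columns {sorted(missing)}")
    splits = []
    all_ids = None
    for sid, grp in df.groupby("split_id", sort=True):
        if grp["record_id"].duplicated().any():
            dup = grp.loc[grp["record_id"].duplicated(), "record_id"].iloc[0]
            raise ValueError(f"split {sid}: record {dup!r} assigned twice")
        s = SplitAssignment(int(sid), dict(zip(grp["record_id"], grp["set_label"])))
        if all_ids is None:
            all_ids = set(s.assignment)
        s.validate(all_ids)
        splits.append(s)
    return splits


def leakage_report(
    smiles_by_id: Mapping[Hashable, str], split: SplitAssignment
) -> List[Tuple[str, List[Hashable]]]:
    """List duplicate SMILES whose copies fall in different sets of a split.

    Such records leak information between training and validation; the
    split generator allows them (the method models strings as given) but
    the user must see them.  Emits a warning when any are found.
    """
    by_smiles: Dict[str, List[Hashable]] = {}
    for rid, smi in smiles_by_id.items():
        by_smiles.setdefault(smi, []).append(rid)
    leaks = [
        (smi, rids)
        for smi, rids in by_smiles.items()
        if len(rids) > 1 and len({split.assignment[r] for r in rids}) > 1
    ]
    if leaks:
        warnings.warn(
            f"{len(leaks)} duplicate SMILES span multiple sets of split "
            f"{split.split_id}",
            stacklevel=2,
        )
    return leaks
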