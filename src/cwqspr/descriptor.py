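"""Correlation-weight storage, the optimal descriptor DCW, and calibration.

The model is a one-descriptor linear regression

    endpoint = C0 + C1 * DCW(T, N)

where DCW is the sum of learnable *correlation weights* over the SMILES
attributes (single tokens and adjacent pairs) of a molecule.  ``T`` is the
rarity threshold that separates *active* attributes (optimized) from
*inactive* ones (pinned to weight 0), and ``N`` is the number of Monte Carlo
epochs; the defaults give the classic DCW(3, 15) descriptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .tokens import AttributeKey, TokenSequence, attribute_counts, tokenize

__all__ = [
    "CWEntry",
    "CorrelationWeightTable",
    "ModelState",
    "classify_active",
    "compute_dcw",
    "fit_regression",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class CWEntry:
    """One attribute's weight, activity flag and occurrence count.

    ``count`` is the number of *distinct* active-training molecules that
    contain the attribute (per-molecule presence, not total occurrences).
    """

    weight: float = 0.0
    active: bool = False
    count: int = 0


class CorrelationWeightTable:
    """Map from :class:`AttributeKey` to :class:`CWEntry`.

    Inactive entries have weight exactly 0 and are never touched by the
    optimizer; attributes absent from the table contribute 0 to DCW.
    """

    def __init__(self, entries: Optional[Dict[AttributeKey, CWEntry]] = None):
        self.entries: Dict[AttributeKey, CWEntry] = dict(entries or {})

    @property
    def nac(self) -> int:
        """Number of active attributes — the optimizer's parameter count."""
        return sum(1 for e in self.entries.values() if e.active)

    def active_keys(self) -> List[AttributeKey]:
        return sorted(k for k, e in self.entries.items() if e.active)

    def weight(self, key: AttributeKey) -> float:
        e = self.entries.get(key)
        return e.weight if e is not None else 0.0

    def set_weight(self, key: AttributeKey, weight: float) -> None:
        e = self.entries[key]
        if not e.active:
            raise ValueError(f"attribute {key.rendered()!r} is inactive; weight is pinned to 0")
        e.weight = float(weight)

    def copy(self) -> "CorrelationWeightTable":
        return CorrelationWeightTable(
            {k: CWEntry(e.weight, e.active, e.count) for k, e in self.entries.items()}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CorrelationWeightTable):
            return NotImplemented
        if set(self.entries) != set(other.entries):
            return False
        return all(
            (a := self.entries[k]).weight == (b := other.entries[k]).weight
            and a.active == b.active
            and a.count == b.count
            for k in self.entries
        )


@dataclass
class ModelState:
    """A fitted correlation-weight model plus its provenance."""

    cw: CorrelationWeightTable
    c0: float
    c1: float
    threshold_t: int = 3
    n_epochs: int = 15
    split_id: Optional[int] = None
    rng_seed: Optional[int] = None
    chosen_epoch: Optional[int] = None

    @property
    def nac(self) -> int:
        return self.cw.nac

    def descriptor_name(self) -> str:
        return f"DCW({self.threshold_t}.{self.n_epochs})"


def classify_active(
    sequences: Sequence[TokenSequence], threshold_t: int = 3
) -> CorrelationWeightTable:
    """Build the weight table from the active-training molecules.

    An attribute is *active* iff it occurs in at least ``threshold_t``
    distinct molecules of the active training set (boundary inclusive).
    Inactive attributes are retained with weight 0 so that the table also
    documents what was seen but considered too rare to parameterize.
    """
    if threshold_t < 1:
        raise ValueError("threshold_t must be >= 1")
    if not sequences:
        raise ValueError("empty active-training set")
    counts: Dict[AttributeKey, int] = {}
    for seq in sequences:
        for key in set(attribute_counts(seq)):
            counts[key] = counts.get(key, 0) + 1
    table = CorrelationWeightTable()
    for key, n in counts.items():
        table.entries[key] = CWEntry(weight=0.0, active=n >= threshold_t, count=n)
    return table


def init_weights(
    table: CorrelationWeightTable,
    mode: str = "ones",
    rng: Optional[np.random.Generator] = None,
) -> None:
    """Initialize active weights in place: ``ones`` (deterministic baseline)
    or ``uniform`` (U(−1, 1) draws from ``rng``, for robustness runs)."""
    if mode == "ones":
        for e in table.entries.values():
            if e.active:
                e.weight = 1.0
    elif mode == "uniform":
        if rng is None:
            raise ValueError("uniform init requires an rng")
        for k in table.active_keys():
            table.entries[k].weight = float(rng.uniform(-1.0, 1.0))
    else:
        raise ValueError(f"unknown init mode {mode!r}")


def compute_dcw(seq: TokenSequence, cw: CorrelationWeightTable) -> float:
    """DCW of one molecule: sum of weights over its attribute multiset.

    Every occurrence counts (a molecule with two nitrogens adds the N weight
    twice); attributes missing from the table contribute 0.
    """
    return float(sum(n * cw.weight(k) for k, n in attribute_counts(seq).items()))


def fit_regression(
    dcw_values: Sequence[float], endpoints: Sequence[float]
) -> Tuple[float, float]:
    """Ordinary least squares of the endpoint on the descriptor.

    Returns ``(c0, c1)`` — intercept and slope.  A zero-variance descriptor
    signals a collapsed weight table and raises.
    """
    x = np.asarray(dcw_values, dtype=float)
    y = np.asarray(endpoints, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("dcw_values and endpoints must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("need at least 3 points to calibrate")
    if np.ptp(x) == 0.0:
        raise ValueError("descriptor has zero variance (collapsed weight table)")
    c1, c0 = np.polyfit(x, y, 1)
    return float(c0), float(c1)


def predict(model: ModelState, seq: TokenSequence) -> float:
    """``c0 + c1 * DCW`` for one molecule."""
    return model.c0 + model.c1 * compute_dcw(seq, model.cw)


def predict_many(model: ModelState, smiles: Iterable[str]) -> np.ndarray:
    return np.array([predict(model, tokenize(s)) for s in smiles])


# ---------------------------------------------------------------------------
# model files
#
# Plain text, tab-separated.  Floats are written with repr() (17 significant
# digits) so a round-tripped model predicts bit-identically.  The dot-padded
# rendered key is included for readability only; the reader parses the raw
# token columns.

_HEADER_FIELDS = ("threshold_t", "n_epochs", "c0", "c1", "nac", "seed", "split_id", "chosen_epoch")


def save_model(model: ModelState, path) -> None:
    lines = ["# correlation-weight model"]
    meta = {
        "threshold_t": model.threshold_t,
        "n_epochs": model.n_epochs,
        "c0": repr(float(model.c0)),
        "c1": repr(float(model.c1)),
        "nac": model.nac,
        "seed": model.rng_seed,
        "split_id": model.split_id,
        "chosen_epoch": model.chosen_epoch,
    }
    for k in _HEADER_FIELDS:
        lines.append(f"{k}\t{meta[k]}")
    # kind column first: rendered keys may themselves start with '#'
    lines.append("# kind\trendered\ttoken1\ttoken2\tcount\tactive\tweight")
    for key in sorted(model.cw.entries):
        e = model.cw.entries[key]
        tok2 = key.symbols[1] if key.kind == "pair" else ""
        lines.append(
            f"{key.kind}\t{key.rendered()}\t{key.symbols[0]}\t{tok2}"
            f"\t{e.count}\t{int(e.active)}\t{repr(float(e.weight))}"
        )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> ModelState:
    meta: Dict[str, str] = {}
    table = CorrelationWeightTable()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                meta[parts[0]] = parts[1]
                continue
            kind, _, tok1, tok2, count, active, weight = parts
            key = AttributeKey.single(tok1) if kind == "single" else AttributeKey.pair(tok1, tok2)
            table.entries[key] = CWEntry(float(weight), bool(int(active)), int(count))

    def _opt_int(s: str) -> Optional[int]:
        return None if s == "None" else int(s)

    return ModelState(
        cw=table,
        c0=float(meta["c0"]),
        c1=float(meta["c1"]),
        threshold_t=int(meta["threshold_t"]),
        n_epochs=int(meta["n_epochs"]),
        split_id=_opt_int(meta["split_id"]),
        rng_seed=_opt_int(meta["seed"]),
        chosen_epoch=_opt_int(meta["chosen_epoch"]),
    )


def model_to_json(model: ModelState) -> str:
    """JSON rendering of a model (an alternative to the text format)."""
    obj = {
        "threshold_t": model.threshold_t,
        "n_epochs": model.n_epochs,
        "c0": model.c0,
        "c1": model.c1,
        "nac": model.nac,
        "seed": model.rng_seed,
        "split_id": model.split_id,
        "chosen_epoch": model.chosen_epoch,
        "attributes": [
            {
                "kind": k.kind,
                "symbols": list(k.symbols),
                "rendered": k.rendered(),
                "count": e.count,
                "active": e.active,
                "weight": e.weight,
            }
            for k, e in sorted(model.cw.entries.items())
        ],
    }
    return json.dumps(obj, indent=1)


def model_from_json(text: str) -> ModelState:
    obj = json.loads(text)
    table = CorrelationWeightTable()
    for a in obj["attributes"]:
        key = (
            AttributeKey.single(a["symbols"][0])
            if a["kind"] == "single"
            else AttributeKey.pair(*a["symbols"])
        )
        table.entries[key] = CWEntry(a["weight"], a["active"], a["count"])
    return ModelState(
        cw=table,
        c0=obj["c0"],
        c1=obj["c1"],
        threshold_t=obj["threshold_t"],
        n_epochs=obj["n_epochs"],
        split_id=obj["split_id"],
        rng_seed=obj["seed"],
        chosen_epoch=obj["chosen_epoch"],
    )
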