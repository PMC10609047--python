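"""Monte Carlo optimization of correlation weights.

The objective is the target function

    TF = r_AT + r_PT − |r_AT − r_PT| · 0.1

where r_AT and r_PT are Pearson correlations between observed and predicted
endpoints on the active and passive training sets.  Only the active training
set drives the regression calibration; the passive term keeps the weights
from fitting A alone, and the calibration set is monitored once per epoch —
the returned model is the snapshot at the epoch where the calibration
correlation peaked, which is where overtraining starts.

An epoch visits every active attribute once, in a seeded random order, and
hill-climbs its weight with random step sizes: a proposal ``w ± δ`` with
δ ~ U(0.01, 0.1) is accepted iff TF strictly increases; on rejection the
opposite sign is tried once, and the first two-sided failure moves on to the
next attribute (with a cap on accepted moves per attribute per epoch).
Changing one weight shifts each molecule's descriptor by count × Δweight, so
proposals are evaluated with O(n) incremental descriptor updates; the full
recomputation is kept as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .descriptor import (
    CorrelationWeightTable,
    ModelState,
    classify_active,
    compute_dcw,
    init_weights,
)
from .splits import SplitAssignment
from .tokens import AttributeKey, TokenSequence, attribute_counts, tokenize

__all__ = [
    "OptimizerConfig",
    "EpochRecord",
    "MonteCarloOptimizer",
    "target_function",
    "optimize",
]


def target_function(r_at: float, r_pt: float) -> float:
    """TF = r_at + r_pt − |r_at − r_pt|·0.1; the penalty vanishes when the
    two training correlations agree."""
    return r_at + r_pt - abs(r_at - r_pt) * 0.1


@dataclass
class OptimizerConfig:
    """Tunable knobs of the Monte Carlo run.

    ``proposal_low/high`` bound the uniform step-size draw (weights live on
    a ~1 scale); ``max_moves_per_attribute`` caps accepted moves during one
    attribute's hill climb within an epoch, bounding epoch cost.
    """

    threshold_t: int = 3
    n_epochs: int = 15
    proposal_low: float = 0.01
    proposal_high: float = 0.1
    init: str = "ones"  # or "uniform"
    max_moves_per_attribute: int = 30


@dataclass
class EpochRecord:
    """Snapshot taken at the end of an epoch (epoch 0 = initialization)."""

    epoch: int
    tf: float
    r_at: float
    r_pt: float
    r_c: float
    weights: np.ndarray  # copy, aligned with the optimizer's active keys
    c0: float
    c1: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx = x - x.mean()
    sy = y - y.mean()
    den = np.sqrt(np.dot(sx, sx) * np.dot(sy, sy))
    if den == 0.0:
        return 0.0
    return float(np.dot(sx, sy) / den)


def _ols(x: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """Closed-form simple OLS; returns (c0, c1)."""
    xm = x.mean()
    ym = y.mean()
    sxx = float(np.dot(x - xm, x - xm))
    if sxx == 0.0:
        raise ZeroDivisionError("zero-variance descriptor")
    c1 = float(np.dot(x - xm, y - ym)) / sxx
    return ym - c1 * xm, c1


class MonteCarloOptimizer:
    """Stateful optimizer over one dataset/split.

    Parameters
    ----------
    smiles, endpoints, record_ids : aligned sequences describing the data.
    split : assignment of every record id to A/P/C/V.
    config : :class:`OptimizerConfig`.
    seed : master seed; split into independent substreams for weight
        initialization, visit order and proposal draws.
    """

    def __init__(
        self,
        smiles: Sequence[str],
        endpoints: Sequence[float],
        record_ids: Sequence,
        split: SplitAssignment,
        config: Optional[OptimizerConfig] = None,
        seed: int = 0,
    ):
        self.config = config or OptimizerConfig()
        self.seed = int(seed)
        self.split = split
        split.validate(record_ids)
        y = np.asarray(endpoints, dtype=float)
        seqs = [tokenize(s) for s in smiles]
        pos = {rid: i for i, rid in enumerate(record_ids)}
        self._idx = {lab: np.array([pos[r] for r in split.ids(lab)]) for lab in "APCV"}
        if self._idx["A"].size == 0:
            raise ValueError("empty active training set")
        self.y = {lab: y[ix] for lab, ix in self._idx.items()}
        self.seqs = seqs

        self.table = classify_active([seqs[i] for i in self._idx["A"]], self.config.threshold_t)
        self.active_keys: List[AttributeKey] = self.table.active_keys()
        if not self.active_keys:
            raise ValueError(
                "no active attributes at threshold "
                f"{self.config.threshold_t} (Nac = 0); nothing to optimize"
            )
        kcol = {k: j for j, k in enumerate(self.active_keys)}
        # per-set dense count matrices over the active attributes
        self.X: Dict[str, np.ndarray] = {}
        for lab, ix in self._idx.items():
            m = np.zeros((ix.size, len(self.active_keys)))
            for row, i in enumerate(ix):
                for key, cnt in attribute_counts(seqs[i]).items():
                    j = kcol.get(key)
                    if j is not None:
                        m[row, j] = cnt
            self.X[lab] = m

        ss_init, ss_order, ss_prop = np.random.SeedSequence(self.seed).spawn(3)
        init_weights(self.table, self.config.init, np.random.default_rng(ss_init))
        self._rng_order = np.random.default_rng(ss_order)
        self._rng_prop = np.random.default_rng(ss_prop)

        self.w = np.array([self.table.entries[k].weight for k in self.active_keys])
        self._dcw = {lab: self.X[lab] @ self.w for lab in "AP"}
        self.epoch = 0
        self.history: List[EpochRecord] = [self._snapshot(0)]
        self.tf = self.history[0].tf

    # -- evaluation helpers -------------------------------------------------

    def _train_eval(self, dcw_a: np.ndarray, dcw_p: np.ndarray):
        """(tf, r_at, r_pt, c0, c1) for candidate descriptor vectors, or
        None when the descriptor is degenerate on A."""
        try:
            c0, c1 = _ols(dcw_a, self.y["A"])
        except ZeroDivisionError:
            return None
        r_at = _pearson(self.y["A"], c0 + c1 * dcw_a)
        r_pt = _pearson(self.y["P"], c0 + c1 * dcw_p)
        return target_function(r_at, r_pt), r_at, r_pt, c0, c1

    def _snapshot(self, epoch: int) -> EpochRecord:
        ev = self._train_eval(self._dcw["A"], self._dcw["P"])
        if ev is None:
            raise ValueError("descriptor has zero variance on the active training set")
        tf, r_at, r_pt, c0, c1 = ev
        r_c = _pearson(self.y["C"], c0 + c1 * (self.X["C"] @ self.w))
        return EpochRecord(epoch, tf, r_at, r_pt, r_c, self.w.copy(), c0, c1)

    # -- the Monte Carlo pass ----------------------------------------------

    def run_epoch(self) -> EpochRecord:
        """One pass over all active attributes; returns the epoch snapshot.

        The sequence of accepted TF values is strictly increasing, so TF at
        the end of the epoch can never be below TF at its start.
        """
        if self.epoch >= self.config.n_epochs:
            raise ValueError("all epochs already run")
        cfg = self.config
        order = self._rng_order.permutation(len(self.active_keys))
        for j in order:
            col_a = self.X["A"][:, j]
            col_p = self.X["P"][:, j]
            for _ in range(cfg.max_moves_per_attribute):
                delta = self._rng_prop.uniform(cfg.proposal_low, cfg.proposal_high)
                if self._rng_prop.random() < 0.5:
                    delta = -delta
                accepted = False
                for step in (delta, -delta):
                    da = self._dcw["A"] + step * col_a
                    dp = self._dcw["P"] + step * col_p
                    ev = self._train_eval(da, dp)
                    if ev is not None and ev[0] > self.tf:
                        self.tf = ev[0]
                        self.w[j] += step
                        self._dcw["A"] = da
                        self._dcw["P"] = dp
                        accepted = True
                        break
                if not accepted:
                    break
        self.epoch += 1
        rec = self._snapshot(self.epoch)
        self.history.append(rec)
        return rec

    def run(self) -> ModelState:
        """Run the configured number of epochs and return the model from the
        epoch with the highest calibration correlation (earliest on ties)."""
        while self.epoch < self.config.n_epochs:
            self.run_epoch()
        best = max(self.history, key=lambda h: (h.r_c, -h.epoch))
        table = self.table.copy()
        for k, wv in zip(self.active_keys, best.weights):
            table.set_weight(k, float(wv))
        return ModelState(
            cw=table,
            c0=best.c0,
            c1=best.c1,
            threshold_t=self.config.threshold_t,
            n_epochs=self.config.n_epochs,
            split_id=self.split.split_id,
            rng_seed=self.seed,
            chosen_epoch=best.epoch,
        )


def optimize(
    smiles: Sequence[str],
    endpoints: Sequence[float],
    record_ids: Sequence,
    split: SplitAssignment,
    config: Optional[OptimizerConfig] = None,
    seed: int = 0,
) -> Tuple[ModelState, List[EpochRecord]]:
    """Convenience wrapper: build the optimizer, run it, return
    ``(model, history)``."""
    opt = MonteCarloOptimizer(smiles, endpoints, record_ids, split, config, seed)
    model = opt.run()
    return model, opt.history
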