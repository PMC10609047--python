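"""Model/Results front end for the correlation-weight QSPR.

:class:`CorrelationWeightModel` is constructed from a dataset and a split,
``fit()`` runs the Monte Carlo optimization, and the returned
:class:`CorrelationWeightResults` carries the fitted state, per-set
statistics and a text ``summary()`` — the familiar model/results idiom.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptor import ModelState, compute_dcw, predict_many, save_model
from .optimizer import EpochRecord, MonteCarloOptimizer, OptimizerConfig
from .splits import SplitAssignment
from .stats import StatReport, stat_report
from .tokens import tokenize

__all__ = ["CorrelationWeightModel", "CorrelationWeightResults"]


class CorrelationWeightModel:
    """One-descriptor QSPR  endpoint = C0 + C1 · DCW(T, N)  over a split.

    Parameters
    ----------
    data : DataFrame with columns ``id``, ``smiles``, ``endpoint``.
    split : the A/P/C/V assignment the model is trained under.
    threshold_t : rarity threshold T separating active from inactive
        attributes (occurrences in distinct active-training molecules).
    n_epochs : number N of Monte Carlo epochs.
    proposal_low, proposal_high, init, max_moves_per_attribute :
        forwarded to :class:`OptimizerConfig`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        split: SplitAssignment,
        threshold_t: int = 3,
        n_epochs: int = 15,
        proposal_low: float = 0.01,
        proposal_high: float = 0.1,
        init: str = "ones",
        max_moves_per_attribute: int = 30,
    ):
        missing = {"id", "smiles", "endpoint"} - set(data.columns)
        if missing:
            raise ValueError(f"data lacks columns {sorted(missing)}")
        self.data = data.reset_index(drop=True)
        self.split = split
        self.config = OptimizerConfig(
            threshold_t=threshold_t,
            n_epochs=n_epochs,
            proposal_low=proposal_low,
            proposal_high=proposal_high,
            init=init,
            max_moves_per_attribute=max_moves_per_attribute,
        )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        split: SplitAssignment,
        smiles_col: str = "smiles",
        endpoint_col: str = "endpoint",
        id_col: str = "id",
        **kwargs,
    ) -> "CorrelationWeightModel":
        data = df.rename(
            columns={smiles_col: "smiles", endpoint_col: "endpoint", id_col: "id"}
        )
        return cls(data, split, **kwargs)

    def fit(self, seed: int = 0) -> "CorrelationWeightResults":
        opt = MonteCarloOptimizer(
            self.data["smiles"].tolist(),
            self.data["endpoint"].to_numpy(),
            self.data["id"].tolist(),
            self.split,
            self.config,
            seed,
        )
        state = opt.run()
        return CorrelationWeightResults(self, state, opt.history)


class CorrelationWeightResults:
    """A fitted correlation-weight model with its diagnostics."""

    def __init__(
        self,
        model: CorrelationWeightModel,
        state: ModelState,
        history: Optional[List[EpochRecord]] = None,
    ):
        self.model = model
        self.state = state
        self.history = history
        self.chosen = None if history is None else history[state.chosen_epoch]

    @classmethod
    def from_state(
        cls, data: pd.DataFrame, split, state: ModelState
    ) -> "CorrelationWeightResults":
        """Wrap a previously saved :class:`ModelState` (e.g. a loaded model
        file) for evaluation on a dataset; no optimization history."""
        shell = CorrelationWeightModel(
            data, split, threshold_t=state.threshold_t, n_epochs=state.n_epochs
        )
        return cls(shell, state)

    # -- basic accessors ----------------------------------------------------

    @property
    def nac(self) -> int:
        return self.state.nac

    @property
    def chosen_epoch(self) -> int:
        return self.state.chosen_epoch

    @property
    def r_at(self) -> float:
        return self.chosen.r_at

    @property
    def r_pt(self) -> float:
        return self.chosen.r_pt

    @property
    def r_c(self) -> float:
        return self.chosen.r_c

    def predict(self, smiles: Optional[Sequence[str]] = None) -> np.ndarray:
        if smiles is None:
            smiles = self.model.data["smiles"]
        return predict_many(self.state, smiles)

    def dcw(self, smiles: Sequence[str]) -> np.ndarray:
        return np.array([compute_dcw(tokenize(s), self.state.cw) for s in smiles])

    def save(self, path) -> None:
        save_model(self.state, path)

    # -- statistics ---------------------------------------------------------

    def _set_frames(self) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
        data = self.model.data.set_index("id")
        out = {}
        for lab in "APCV":
            ids = self.model.split.ids(lab)
            obs = data.loc[ids, "endpoint"].to_numpy()
            pred = self.predict(data.loc[ids, "smiles"])
            out[lab] = (obs, pred)
        return out

    def stats(self) -> List[Tuple[int, str, StatReport]]:
        """Per-set statistics panel; the calibration set additionally gets
        the external criteria against the active-training reference, and the
        validation row carries Nac."""
        frames = self._set_frames()
        obs_a = frames["A"][0]
        rows = []
        for lab in "APCV":
            obs, pred = frames[lab]
            rep = stat_report(
                obs,
                pred,
                obs_train=obs_a if lab == "C" else None,
                nac=self.nac if lab == "V" else None,
            )
            rows.append((self.model.split.split_id, lab, rep))
        return rows

    def stats_frame(self) -> pd.DataFrame:
        recs = []
        for split_id, lab, r in self.stats():
            recs.append(
                {
                    "split": split_id,
                    "set": lab,
                    "n": r.n,
                    "R2": r.r2,
                    "CCC": r.ccc,
                    "Q2F1": r.q2f1,
                    "Q2F2": r.q2f2,
                    "Q2F3": r.q2f3,
                    "avg_Rm2": r.avg_rm2,
                    "RMSE": r.rmse,
                    "MAE": r.mae,
                    "F": r.f_ratio,
                    "Nac": r.nac,
                }
            )
        return pd.DataFrame(recs)

    def coefficient_standard_errors(self) -> Tuple[float, float]:
        """OLS standard errors of (c0, c1) on the active training set."""
        data = self.model.data.set_index("id")
        ids = self.model.split.ids("A")
        x = self.dcw(data.loc[ids, "smiles"])
        y = data.loc[ids, "endpoint"].to_numpy()
        n = x.size
        resid = y - (self.state.c0 + self.state.c1 * x)
        s2 = float(np.dot(resid, resid)) / (n - 2)
        sxx = float(np.dot(x - x.mean(), x - x.mean()))
        se_c1 = np.sqrt(s2 / sxx)
        se_c0 = np.sqrt(s2 * (1.0 / n + x.mean() ** 2 / sxx))
        return float(se_c0), float(se_c1)

    def summary(self) -> str:
        """Readable report: the model equation with coefficient standard
        errors, provenance, and the four-set statistics table."""
        se0, se1 = self.coefficient_standard_errors()
        s = self.state
        lines = [
            "Correlation-weight QSPR results",
            "=" * 55,
            f"endpoint = {s.c0:.4f} (±{se0:.4f}) + {s.c1:.4f} (±{se1:.4f}) × {s.descriptor_name()}",
            f"split {s.split_id}   seed {s.rng_seed}   Nac {s.nac}   "
            f"chosen epoch {s.chosen_epoch}/{s.n_epochs}",
            f"r(A) = {self.r_at:.4f}   r(P) = {self.r_pt:.4f}   r(C) = {self.r_c:.4f}",
            "",
        ]
        df = self.stats_frame()
        with pd.option_context("display.float_format", lambda v: f"{v:.4f}"):
            lines.append(df.to_string(index=False))
        return "\n".join(lines)
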