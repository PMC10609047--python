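"""The system of self-consistent models (SCM).

Given n independent random splits and the n models trained on them, every
model i is applied to every split k's validation set *after removing the
compounds that model i saw* — i.e. those in split i's active training,
passive training or calibration sets.  Because the four sets partition the
data, the surviving compounds are exactly V_k ∩ V_i, so the count matrix is
symmetric with |V_i| on the diagonal.  The spread of the resulting n×n
determination coefficients measures how much the method's apparent
predictive potential depends on the particular split — the self-consistency
of the modelling approach, as opposed to the luck of one split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .descriptor import ModelState, predict_many
from .splits import SplitAssignment
from .stats import basic_stats

__all__ = [
    "ScmResult",
    "validation_subset",
    "build_scm",
    "row_summary",
    "nac_correlation",
    "write_scm_tables",
]


def validation_subset(
    split_k: SplitAssignment,
    split_i: SplitAssignment,
    smiles_by_id: Optional[Mapping[Hashable, str]] = None,
) -> List[Hashable]:
    """Compounds of split k's validation set unseen by split i's model:
    V_k minus (A_i ∪ P_i ∪ C_i).  For i = k this is all of V_k.

    Exclusion is by record identity; pass ``smiles_by_id`` to exclude by
    SMILES-string identity instead, so that duplicate structures seen
    under a different record id are also removed.
    """
    if set(split_k.assignment) != set(split_i.assignment):
        raise ValueError("splits cover different record sets")
    seen = {
        rid for rid, lab in split_i.assignment.items() if lab in ("A", "P", "C")
    }
    if smiles_by_id is None:
        return [rid for rid in split_k.ids("V") if rid not in seen]
    seen_smiles = {smiles_by_id[rid] for rid in seen}
    return [rid for rid in split_k.ids("V") if smiles_by_id[rid] not in seen_smiles]


def row_summary(values: Sequence[float]) -> Tuple[float, float]:
    """Mean and dispersion (population standard deviation, divisor n) of a
    row of determination coefficients, ignoring missing (NaN) cells."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan"), float("nan")
    return float(v.mean()), float(v.std())


def nac_correlation(nac: Sequence[float], row_means: Sequence[float]) -> Optional[float]:
    """Pearson correlation between each model's number of active attributes
    and its mean validation R².  Returns None (missing) when either vector
    is constant; empirically this correlation comes out negative — fewer
    optimized parameters, better predictive potential."""
    a = np.asarray(nac, dtype=float)
    b = np.asarray(row_means, dtype=float)
    if a.size < 3 or a.size != b.size:
        raise ValueError("need >= 3 paired values")
    if np.ptp(a) == 0.0 or np.ptp(b) == 0.0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class ScmResult:
    """n×n cross-validation matrices and their per-model summaries."""

    n_models: int
    count_matrix: np.ndarray  # int, diagonal |V_i|, symmetric
    r2_matrix: np.ndarray  # NaN marks a missing (empty-subset) cell
    mae_matrix: np.ndarray
    row_means: np.ndarray
    row_sds: np.ndarray
    nac_vector: np.ndarray
    nac_r2_correlation: Optional[float]
    missing_cells: List[Tuple[int, int]] = field(default_factory=list)

    def validate(self) -> None:
        """Assert the structural laws of the count matrix."""
        c = self.count_matrix
        if not np.array_equal(c, c.T):
            bad = np.argwhere(c != c.T)
            raise AssertionError(f"count matrix asymmetric at cells {bad[:4].tolist()}")

    def scatter_table(self) -> pd.DataFrame:
        """(model, Nac, mean R²) table for the anti-correlation scatter."""
        return pd.DataFrame(
            {
                "model": [f"M{i+1}" for i in range(self.n_models)],
                "nac": self.nac_vector,
                "mean_r2": self.row_means,
            }
        )


def build_scm(
    models: Sequence[ModelState],
    splits: Sequence[SplitAssignment],
    smiles_by_id: Mapping[Hashable, str],
    endpoint_by_id: Mapping[Hashable, float],
    exclude_by: str = "record",
) -> ScmResult:
    """Cross-apply every model to every split's reduced validation set.

    ``models[i]`` must be the model trained on ``splits[i]``.  Empty
    off-diagonal subsets are recorded as missing, excluded from the row
    summaries, and warned about — they never crash the summary.
    ``exclude_by`` is ``record`` (default; set algebra on ids, count
    matrix provably symmetric) or ``smiles`` (duplicate structures seen
    under another id are excluded too; symmetry is not guaranteed and is
    not asserted).
    """
    if len(models) != len(splits):
        raise ValueError("one model per split required")
    if exclude_by not in ("record", "smiles"):
        raise ValueError(f"unknown exclusion mode {exclude_by!r}")
    by_smiles = smiles_by_id if exclude_by == "smiles" else None
    n = len(models)
    counts = np.zeros((n, n), dtype=int)
    r2 = np.full((n, n), np.nan)
    mae = np.full((n, n), np.nan)
    missing: List[Tuple[int, int]] = []
    pred_cache: Dict[Tuple[int, Hashable], float] = {}
    for i in range(n):
        for k in range(n):
            ids = validation_subset(splits[k], splits[i], by_smiles)
            counts[i, k] = len(ids)
            if not ids:
                missing.append((i, k))
                continue
            todo = [rid for rid in ids if (i, rid) not in pred_cache]
            if todo:
                vals = predict_many(models[i], [smiles_by_id[r] for r in todo])
                pred_cache.update({(i, r): v for r, v in zip(todo, vals)})
            pred = np.array([pred_cache[(i, r)] for r in ids])
            obs = np.array([endpoint_by_id[r] for r in ids])
            try:
                cell_r2, _, cell_mae, _, _ = basic_stats(obs, pred)
            except ValueError:  # subset too small or degenerate for R²
                missing.append((i, k))
                continue
            r2[i, k] = cell_r2
            mae[i, k] = cell_mae
    if missing:
        warnings.warn(f"{len(missing)} empty SCM cells recorded as missing", stacklevel=2)
    means = np.empty(n)
    sds = np.empty(n)
    for i in range(n):
        means[i], sds[i] = row_summary(r2[i])
    result = ScmResult(
        n_models=n,
        count_matrix=counts,
        r2_matrix=r2,
        mae_matrix=mae,
        row_means=means,
        row_sds=sds,
        nac_vector=np.array([m.nac for m in models]),
        nac_r2_correlation=nac_correlation([m.nac for m in models], means)
        if n >= 3
        else None,
        missing_cells=missing,
    )
    if exclude_by == "record":
        result.validate()
    return result


def _matrix_frame(m: np.ndarray, n: int, fmt=None) -> pd.DataFrame:
    df = pd.DataFrame(
        m,
        index=[f"M{i+1}" for i in range(n)],
        columns=[f"S{k+1}" for k in range(n)],
    )
    return df if fmt is None else df.map(fmt)


def write_scm_tables(result: ScmResult, outdir) -> Dict[str, pd.DataFrame]:
    """Write the three cross-matrices and the Nac scatter as TSV files.

    The R² table carries an extra ``mean ± SD`` summary column; layouts use
    rows M1…Mn (models) against columns S1…Sn (splits).
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    n = result.n_models
    tables = {
        "counts": _matrix_frame(result.count_matrix, n),
        "mae": _matrix_frame(np.round(result.mae_matrix, 2), n),
    }
    r2df = _matrix_frame(np.round(result.r2_matrix, 4), n)
    r2df["mean_sd"] = [
        f"{m:.4f} ± {s:.4f}" for m, s in zip(result.row_means, result.row_sds)
    ]
    tables["r2"] = r2df
    tables["nac_scatter"] = result.scatter_table()
    for name, df in tables.items():
        df.to_csv(
            os.path.join(outdir, f"scm_{name}.tsv"),
            sep="\t",
            index=name != "nac_scatter",
            index_label="" if name != "nac_scatter" else None,
        )
    return tables
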