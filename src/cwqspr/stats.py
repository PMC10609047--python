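"""QSPR validation statistics for (observed, predicted) endpoint vectors.

Implements the panel conventionally reported for correlation-weight models:
determination coefficient R² (squared Pearson r), Lin's concordance
correlation coefficient (CCC), the external predictive-squared-correlation
criteria Q²F1/Q²F2/Q²F3, the averaged rm² metric, RMSE, MAE and the Fisher
F ratio.  All second moments are population (1/n) moments, the common QSAR
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StatReport",
    "basic_stats",
    "external_q2",
    "avg_rm2",
    "stat_report",
    "write_report",
]


def _as_vec(x, name: str, n_min: int = 3) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if v.size < n_min:
        raise ValueError(f"{name} needs at least {n_min} values")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def basic_stats(obs, pred) -> Tuple[float, float, float, float, float]:
    """Return ``(r2, rmse, mae, f_ratio, ccc)``.

    * r2 — squared Pearson correlation;
    * rmse, mae — in endpoint units;
    * f_ratio — (n − 2)·r²/(1 − r²), infinite for a perfect fit;
    * ccc — Lin's concordance, 2·cov/(var_o + var_p + (mean_o − mean_p)²).
    """
    o = _as_vec(obs, "obs")
    p = _as_vec(pred, "pred")
    if o.size != p.size:
        raise ValueError("obs and pred differ in length")
    n = o.size
    if np.ptp(o) == 0.0:
        raise ValueError("observed values have zero variance")
    resid = o - p
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.ptp(p) == 0.0:
        r2 = 0.0
        ccc_r = 0.0
    else:
        r = float(np.corrcoef(o, p)[0, 1])
        r2 = r * r
        cov = float(np.mean((o - o.mean()) * (p - p.mean())))
        ccc_r = 2.0 * cov / (o.var() + p.var() + (o.mean() - p.mean()) ** 2)
    f_ratio = float("inf") if r2 >= 1.0 else (n - 2) * r2 / (1.0 - r2)
    return r2, rmse, mae, float(f_ratio), float(ccc_r)


def external_q2(obs_ext, pred_ext, obs_train) -> Tuple[float, float, float]:
    """External predictive criteria ``(q2f1, q2f2, q2f3)``.

    With PRESS = Σ(obs_ext − pred_ext)²:

    * Q²F1 = 1 − PRESS / Σ(obs_ext − mean(obs_train))²
    * Q²F2 = 1 − PRESS / Σ(obs_ext − mean(obs_ext))²
    * Q²F3 = 1 − [PRESS/n_ext] / [Σ(obs_train − mean(obs_train))²/n_train]

    They differ only in the reference variance; the training set is the one
    the model was calibrated on.
    """
    oe = _as_vec(obs_ext, "obs_ext")
    pe = _as_vec(pred_ext, "pred_ext")
    ot = _as_vec(obs_train, "obs_train")
    if oe.size != pe.size:
        raise ValueError("obs_ext and pred_ext differ in length")
    press = float(np.sum((oe - pe) ** 2))
    ss_f1 = float(np.sum((oe - ot.mean()) ** 2))
    ss_f2 = float(np.sum((oe - oe.mean()) ** 2))
    ss_tr = float(np.sum((ot - ot.mean()) ** 2))
    if ss_f1 == 0.0 or ss_f2 == 0.0 or ss_tr == 0.0:
        raise ValueError("degenerate reference set (zero variance)")
    q2f1 = 1.0 - press / ss_f1
    q2f2 = 1.0 - press / ss_f2
    q2f3 = 1.0 - (press / oe.size) / (ss_tr / ot.size)
    return q2f1, q2f2, q2f3


def _rm2_one_way(x: np.ndarray, y: np.ndarray) -> float:
    """rm² of y against x: r²·(1 − √(r² − r0²)) with r0² the determination
    coefficient of the through-origin fit of y on x."""
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = r * r
    k = float(np.dot(x, y) / np.dot(x, x))
    ss_res = float(np.sum((y - k * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r02 = 1.0 - ss_res / ss_tot
    rad = r2 - r02
    if rad < 0.0:
        warnings.warn("negative rm2 radicand clipped to 0", stacklevel=3)
        rad = 0.0
    return r2 * (1.0 - np.sqrt(rad))


def avg_rm2(obs, pred) -> float:
    """⟨rm²⟩: mean of rm² computed both ways (and with axes swapped).

    Penalizes predictions whose best through-origin fit deviates from the
    free regression; equals r² = 1 only for perfect predictions.
    """
    o = _as_vec(obs, "obs")
    p = _as_vec(pred, "pred")
    if o.size != p.size:
        raise ValueError("obs and pred differ in length")
    if np.ptp(o) == 0.0 or np.ptp(p) == 0.0:
        raise ValueError("zero-variance input to avg_rm2")
    return float(0.5 * (_rm2_one_way(o, p) + _rm2_one_way(p, o)))


@dataclass
class StatReport:
    """Full statistics panel for one (set, model) evaluation."""

    n: int
    r2: float
    ccc: float
    rmse: float
    mae: float
    f_ratio: float
    q2f1: Optional[float] = None
    q2f2: Optional[float] = None
    q2f3: Optional[float] = None
    avg_rm2: Optional[float] = None
    nac: Optional[int] = None


def stat_report(obs, pred, obs_train=None, nac: Optional[int] = None) -> StatReport:
    """Compute the panel; pass ``obs_train`` to add the external criteria
    (Q²F1–F3 and ⟨rm²⟩), conventionally reported for the calibration set
    against the active-training reference."""
    o = _as_vec(obs, "obs")
    r2, rmse, mae, f_ratio, ccc = basic_stats(obs, pred)
    rep = StatReport(n=o.size, r2=r2, ccc=ccc, rmse=rmse, mae=mae, f_ratio=f_ratio, nac=nac)
    if obs_train is not None:
        rep.q2f1, rep.q2f2, rep.q2f3 = external_q2(obs, pred, obs_train)
        rep.avg_rm2 = avg_rm2(obs, pred)
    return rep


def write_report(reports: Sequence[Tuple[int, str, StatReport]], path) -> pd.DataFrame:
    """Write a delimited statistics table, one row per (split, set).

    ``reports`` holds (split_id, set_label, StatReport) triples; the column
    layout mirrors the conventional per-split quality table.
    """
    rows = []
    for split_id, set_label, r in reports:
        rows.append(
            {
                "split": split_id,
                "set": set_label,
                "n": r.n,
                "R2": round(r.r2, 4),
                "CCC": round(r.ccc, 4),
                "Q2F1": None if r.q2f1 is None else round(r.q2f1, 4),
                "Q2F2": None if r.q2f2 is None else round(r.q2f2, 4),
                "Q2F3": None if r.q2f3 is None else round(r.q2f3, 4),
                "avg_Rm2": None if r.avg_rm2 is None else round(r.avg_rm2, 4),
                "RMSE": round(r.rmse, 2),
                "MAE": round(r.mae, 2),
                "F": None if not np.isfinite(r.f_ratio) else int(round(r.f_ratio)),
                "Nac": r.nac,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
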