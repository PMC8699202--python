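"""Accuracy measures for CCS prediction.

Seven measures: RMSE and MAE in Angstrom^2; MPE, MdPE and Delta90 as the
mean, median and 90th percentile of the absolute percentage errors
100*|pred - ref|/ref; the coefficient of determination R^2; and Pearson's r.
Percentile uses linear interpolation between order statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError


@dataclass(frozen=True)
class EvaluationReport:
    rmse: float
    mae: float
    mpe: float
    mdpe: float
    delta90: float
    r2: float
    pearson_r: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "n": self.n,
            "rmse_a2": self.rmse,
            "mae_a2": self.mae,
            "mpe_pct": self.mpe,
            "mdpe_pct": self.mdpe,
            "delta90_pct": self.delta90,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
        }


def percentage_errors(pred: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Absolute percentage errors, 100*|pred - ref|/ref."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have equal length")
    if np.any(ref <= 0):
        raise DegenerateInputError("reference CCS values must be positive")
    return 100.0 * np.abs(pred - ref) / ref


def evaluate(pred: np.ndarray, ref: np.ndarray) -> EvaluationReport:
    """Compute all seven accuracy measures for one set of predictions."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    if pred.size < 2:
        raise DegenerateInputError("need at least 2 records to evaluate")
    pe = percentage_errors(pred, ref)
    resid = pred - ref
    if np.ptp(ref) == 0:
        # error/percentage measures remain defined; correlation measures do not
        warnings.warn("constant reference values: R^2 and r are undefined", stacklevel=2)
        r2 = pearson = float("nan")
    else:
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((ref - ref.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot
        pearson = float(stats.pearsonr(pred, ref).statistic)
    return EvaluationReport(
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
        mpe=float(np.mean(pe)),
        mdpe=float(np.median(pe)),
        delta90=float(np.percentile(pe, 90)),
        r2=r2,
        pearson_r=pearson,
        n=int(pred.size),
    )


#: CCS strata used for range-resolved reports, in Angstrom^2
DEFAULT_CCS_BINS = (0.0, 400.0, 800.0, 1200.0)


def evaluate_by_group(
    pred: np.ndarray, ref: np.ndarray, groups: np.ndarray
) -> dict[object, EvaluationReport]:
    """Per-group evaluation (e.g. by charge state); groups with <2 records
    or constant reference are skipped."""
    pred = np.asarray(pred, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    groups = np.asarray(groups)
    out: dict[object, EvaluationReport] = {}
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() < 2 or np.ptp(ref[mask]) == 0:
            continue
        out[g.item() if hasattr(g, "item") else g] = evaluate(pred[mask], ref[mask])
    return out


def evaluate_by_ccs_range(
    pred: np.ndarray, ref: np.ndarray, bins: tuple[float, ...] = DEFAULT_CCS_BINS
) -> dict[str, EvaluationReport]:
    """Evaluation stratified by reference-CCS bins (right-open intervals)."""
    ref = np.asarray(ref, dtype=np.float64)
    idx = np.digitize(ref, bins[1:], right=False)
    labels = [f"{bins[i]:g}-{bins[i + 1]:g}" for i in range(len(bins) - 1)] + [
        f">{bins[-1]:g}"
    ]
    groups = np.array([labels[i] for i in idx])
    return evaluate_by_group(pred, ref, groups)
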