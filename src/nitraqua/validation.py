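"""Leave-one-out cross-validation and the error statistics used to rank
interpolation methods.

Each interpolator is scored by refitting on n-1 samples and predicting
the held-out observation; RMSE, %RMSE (RMSE over the observed mean) and
MRE (mean absolute relative error) summarize the residuals. Points the
natural-neighbour method cannot estimate (outside the reduced convex
hull) are excluded from that method's statistics and counted, not
imputed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import SampleTable
from .interpolation import InterpolatorSpec, make_interpolator


@dataclass(frozen=True)
class CvResult:
    """Cross-validation summary for one interpolation method.

    ``residuals`` are predicted minus observed (mg/L) in input order,
    NaN where the point was inestimable; ``pct_rmse`` is stored as a
    fraction (multiply by 100 for the percent form).
    """

    method: str
    residuals: np.ndarray
    mre: float
    rmse: float
    pct_rmse: float
    n_evaluated: int
    n_excluded: int


def rmse(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Root mean squared error sqrt(mean((predicted - observed)^2))."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((p - o) ** 2)))


def pct_rmse(rmse_value: float, mean_observed: float, as_percent: bool = False) -> float:
    """RMSE normalized by the observed mean.

    Returns the fraction by default (the scale error tables typically
    print); ``as_percent=True`` multiplies by 100.
    """
    if mean_observed == 0:
        raise ValueError("pct_rmse undefined for zero mean")
    out = rmse_value / mean_observed
    return out * 100.0 if as_percent else out


def mre(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean absolute relative error: mean of |(pred - obs)/obs|."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if p.size == 0:
        raise ValueError("need at least one pair")
    if np.any(o == 0):
        raise ValueError("mre undefined when an observed value is 0")
    return float(np.mean(np.abs((p - o) / o)))


def loocv(samples: SampleTable, spec: InterpolatorSpec) -> CvResult:
    """Leave-one-out cross-validation of one interpolator.

    For each sample the interpolator is rebuilt from the remaining n-1
    points (including, for kriging without a fixed variogram, the
    variogram fit) and evaluated at the held-out location. Statistics
    are computed over the evaluated points only.
    """
    n = len(samples)
    if n < 4:
        raise ValueError("LOOCV needs at least 4 samples")
    obs = samples.nitrate
    xy = samples.xy
    residuals = np.full(n, np.nan)
    preds = np.full(n, np.nan)
    for i in range(n):
        reduced = samples.drop(i)
        predict = make_interpolator(reduced, spec)
        v = predict((xy[i, 0], xy[i, 1]))
        if math.isfinite(v):
            preds[i] = v
            residuals[i] = v - obs[i]
    evaluated = np.isfinite(preds)
    n_eval = int(evaluated.sum())
    if n_eval == 0:
        raise ValueError("no fold could be estimated")
    p, o = preds[evaluated], obs[evaluated]
    r = rmse(p, o)
    # MRE divides by the observed value, so zero observations (possible
    # for truncated concentrations) are excluded from it, not from RMSE
    nz = o != 0
    return CvResult(
        method=spec.method,
        residuals=residuals,
        mre=mre(p[nz], o[nz]) if nz.any() else float("nan"),
        rmse=r,
        pct_rmse=pct_rmse(r, float(o.mean())),
        n_evaluated=n_eval,
        n_excluded=n - n_eval,
    )


def rank_methods(
    results: Sequence[CvResult], criterion: str = "rmse"
) -> list[str]:
    """Method names ordered best-first (ascending) by the chosen error.

    Ties are broken by the other criterion, then alphabetically by
    method name.
    """
    if criterion not in ("mre", "rmse"):
        raise ValueError("criterion must be 'mre' or 'rmse'")
    if len(results) == 0:
        raise ValueError("rank_methods needs at least one result")
    other = "rmse" if criterion == "mre" else "mre"
    ordered = sorted(
        results, key=lambda r: (getattr(r, criterion), getattr(r, other), r.method)
    )
    return [r.method for r in ordered]


def write_cv_report(results: Sequence[CvResult], path: str | Path) -> None:
    """Write the cross-validation comparison as a CSV report."""
    df = pd.DataFrame(
        [
            {
                "method": r.method,
                "n_evaluated": r.n_evaluated,
                "mre": round(r.mre, 6),
                "rmse": round(r.rmse, 6),
                "pct_rmse": round(r.pct_rmse, 6),
            }
            for r in results
        ]
    )
    df.to_csv(path, index=False)
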