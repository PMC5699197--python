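"""Quality-control indicators and group statistics for nitrate monitoring.

Precision is expressed as the relative standard deviation of triplicate
measurements, accuracy as percent recovery of certified reference
samples, and sensitivity as a detection-limit check against one tenth of
the water-quality objective. The two-sample comparison between climates
uses the Welch (unequal-variance) t statistic; land-use groups are
compared with a classical one-way ANOVA. Both test statistics are
computed from their defining formulas; p-values come from the t and F
distribution CDFs expressed through the regularized incomplete beta
function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

# Lab acceptance window for percent recovery of spiked reference samples.
RECOVERY_LIMITS = (85.0, 115.0)


@dataclass(frozen=True)
class Triplicate:
    """Three repeated measurements of a certified reference sample.

    ``true_value`` is the certified concentration (mg/L); the replicate
    mean is the measured concentration used for the recovery indicator.
    """

    true_value: float
    replicates: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.replicates) != 3:
            raise ValueError("a Triplicate holds exactly 3 replicates")
        if self.true_value < 0 or any(r < 0 for r in self.replicates):
            raise ValueError("concentrations must be >= 0 mg/L")

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one group of measurements (mg/L)."""

    n: int
    mean: float
    sd: float
    stderr: float
    ci95_lo: float
    ci95_hi: float


@dataclass(frozen=True)
class CfrInputs:
    """Inputs to the calculated-fixed-radius wellhead protection formula.

    pumping_rate Q in m³/year, pumping_time t in years, porosity n as a
    fraction, saturated_thickness H in metres.
    """

    pumping_rate: float
    pumping_time: float
    porosity: float
    saturated_thickness: float

    def __post_init__(self) -> None:
        for name in ("pumping_rate", "pumping_time", "porosity", "saturated_thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.porosity >= 1:
            raise ValueError("porosity is a fraction and must be < 1")


class Recovery(NamedTuple):
    percent: float
    acceptable: bool


class TTestResult(NamedTuple):
    statistic: float
    pvalue: float
    df: float


class AnovaResult(NamedTuple):
    ss_between: float
    df_between: int
    ms_between: float
    ss_within: float
    df_within: int
    ms_within: float
    F: float
    pvalue: float


def rsd(values: Sequence[float], as_percent: bool = False) -> float:
    """Relative standard deviation sd/mean of repeated measurements.

    Uses the sample (n-1) standard deviation. Returns the fraction by
    default; ``as_percent=True`` multiplies by 100. Scale-invariant:
    rsd(c*v) == rsd(v) for c > 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("rsd needs at least 2 values")
    m = float(np.mean(v))
    if m == 0:
        raise ValueError("rsd undefined for zero mean")
    out = float(np.std(v, ddof=1)) / m
    return out * 100.0 if as_percent else out


def recovery(
    true_value: float, measured_mean: float, convention: str = "reported"
) -> Recovery:
    """Percent recovery of a certified reference (spiked) sample.

    ``convention="reported"`` returns measured/true x 100, the form the
    accepted recovery tables use; ``convention="eq2"`` returns
    (true - measured)/true x 100, an alternative error-style convention
    (negative for over-recovery). The ``acceptable`` flag marks the
    85-115% lab window (reported scale; for eq2 the equivalent |value|
    <= 15% window is used).
    """
    if true_value <= 0:
        raise ValueError("true_value must be > 0")
    if convention == "reported":
        pct = measured_mean / true_value * 100.0
        ok = RECOVERY_LIMITS[0] <= pct <= RECOVERY_LIMITS[1]
    elif convention == "eq2":
        pct = (true_value - measured_mean) / true_value * 100.0
        ok = abs(pct) <= 100.0 - RECOVERY_LIMITS[0]
    else:
        raise ValueError(f"unknown recovery convention {convention!r}")
    return Recovery(pct, ok)


def group_summary(values: Sequence[float], confidence: float = 0.95) -> GroupSummary:
    """Mean, sd, standard error and t-based confidence interval."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("group_summary needs n >= 2")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    stderr = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    half = tcrit * stderr
    return GroupSummary(n, mean, sd, stderr, mean - half, mean + half)


def _t_sf_two_sided(t: float, df: float) -> float:
    """Two-sided p for a t statistic via the regularized incomplete beta."""
    if math.isinf(t):
        return 0.0
    x = df / (df + t * t)
    return float(special.betainc(df / 2.0, 0.5, x))


def two_sample_ttest(a: Sequence[float], b: Sequence[float]) -> TTestResult:
    """Welch unequal-variance two-sample t test, two-sided.

    Degenerate case: if both groups have zero variance and equal means,
    t = 0 and p = 1 by convention; zero variance with unequal means
    gives an infinite statistic and p = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    ma, mb = float(np.mean(a)), float(np.mean(b))
    va, vb = float(np.var(a, ddof=1)), float(np.var(b, ddof=1))
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    if se2 == 0.0:
        if ma == mb:
            return TTestResult(0.0, 1.0, float(na + nb - 2))
        return TTestResult(math.copysign(math.inf, ma - mb), 0.0, float(na + nb - 2))
    t = (ma - mb) / math.sqrt(se2)
    # Welch–Satterthwaite degrees of freedom
    df = se2 * se2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return TTestResult(t, _t_sf_two_sided(t, df), df)


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way analysis of variance across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("oneway_anova needs >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 1 for a in arrs):
        raise ValueError("every group needs n >= 1")
    k = len(arrs)
    n_total = sum(a.size for a in arrs)
    if n_total <= k:
        raise ValueError("total n must exceed the number of groups")
    grand = float(np.concatenate(arrs).mean())
    ss_between = float(sum(a.size * (a.mean() - grand) ** 2 for a in arrs))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0 and ss_between == 0.0:
        raise ValueError("all observations identical; F is undefined")
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0.0:
        return AnovaResult(ss_between, df_b, ms_b, ss_within, df_w, ms_w, math.inf, 0.0)
    F = ms_b / ms_w
    x = df_w / (df_w + df_b * F)
    p = float(special.betainc(df_w / 2.0, df_b / 2.0, x))
    return AnovaResult(ss_between, df_b, ms_b, ss_within, df_w, ms_w, F, p)


def cfr_radius(inputs: CfrInputs) -> float:
    """Calculated fixed radius (m) of a wellhead protection zone.

    Volumetric balance: the cylinder of aquifer drained over the pumping
    time equals the pumped volume, r = sqrt(Q t / (pi n H)).
    """
    q, t = inputs.pumping_rate, inputs.pumping_time
    n, h = inputs.porosity, inputs.saturated_thickness
    return math.sqrt(q * t / (math.pi * n * h))


def detection_limit_check(detection_limit: float, objective: float) -> bool:
    """Sensitivity criterion: the instrument detection limit must be at
    least 10x below the water-quality objective (boundary inclusive)."""
    if detection_limit <= 0 or objective <= 0:
        raise ValueError("detection limit and objective must be positive")
    return detection_limit <= objective / 10.0


def assess_triplicate(trip: Triplicate) -> dict[str, float | bool]:
    """Precision (RSD) and accuracy (recovery) indicators for one triplicate."""
    rec = recovery(trip.true_value, trip.mean)
    return {
        "true_value": trip.true_value,
        "mean": trip.mean,
        "sd": trip.sd,
        "rsd": rsd(trip.replicates),
        "recovery_pct": rec.percent,
        "recovery_acceptable": rec.acceptable,
    }


def read_triplicates_csv(path: str | Path) -> list[Triplicate]:
    """Read a QA triplicate file: CSV with columns true_value,rep1,rep2,rep3."""
    df = pd.read_csv(path)
    needed = ["true_value", "rep1", "rep2", "rep3"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return [
        Triplicate(float(r.true_value), (float(r.rep1), float(r.rep2), float(r.rep3)))
        for r in df.itertuples()
    ]
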