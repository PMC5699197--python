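"""Parametric groundwater-vulnerability indices for nitrate.

IPNOA scores the hazard from agriculture: three additive hazard factors
(mineral fertilizer HF_f, organic fertilizer/manure HF_m, sewage sludge
HF_s, each a 1-5 band score of the application rate in kg/ha) are
multiplied by four control factors (soil nitrogen CF_n, climate CF_c,
agronomic practice CF_ap, irrigation CF_i, each a multiplier near 1):

    HI = (HF_f + HF_m + HF_s) * CF_n * CF_c * CF_ap * CF_i

and the product is binned into six classes from "Unlikely" to
"Very high".

IPNOC estimates the companion hazard from civil (sewer) sources as the
annual nitrogen leaking from the network: for each zone the age-adjusted
leakage fraction L_c = L_e * age/life multiplies the transiting nitrogen
load N_i and the pipe length L_i. The literal sum has units kg*m/year;
a per-metre-normalized variant (kg/year) is also returned because the
published form of the sum is dimensionally ambiguous.

All score tables are loaded from a packaged, editable YAML file so that
regional recalibrations do not require code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import pandas as pd
import yaml

IRRIGATION_SYSTEMS = ("basin", "border", "sprinkler", "none")
TILLAGE_PATTERNS = ("traditional", "minimum", "no_tillage")
FERT_APPLICATIONS = ("fertirrigation", "total_surface", "through_leaves", "localized")
FERT_KINDS = ("inorganic", "organic", "sludge")


@lru_cache(maxsize=1)
def load_score_tables() -> dict:
    """Load the packaged IPNOA score tables (hazard bands, control
    factors and classification bands)."""
    text = resources.files("nitraqua.config").joinpath("ipnoa_scores.yaml").read_text()
    return yaml.safe_load(text)


@dataclass(frozen=True)
class IpnoaInputs:
    """Raw inputs to IPNOA scoring for one land-use class.

    Fertilization rates in kg/ha (a (lo, hi) range is scored at its
    midpoint), soil_n in % nitrogen, rainfall in mm/year, temperature
    in deg C; irrigation/tillage/fert_application are closed
    vocabularies.
    """

    inorganic_fert: float | tuple[float, float]
    organic_fert: float | tuple[float, float]
    sludge: float | tuple[float, float]
    soil_n: float
    irrigation: str
    rainfall: float
    temperature: float
    tillage: str
    fert_application: str

    def __post_init__(self) -> None:
        for name in ("inorganic_fert", "organic_fert", "sludge"):
            if _midpoint(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be >= 0 kg/ha")
        if self.soil_n < 0 or self.rainfall < 0:
            raise ValueError("soil_n and rainfall must be >= 0")
        if self.irrigation not in IRRIGATION_SYSTEMS:
            raise ValueError(f"unknown irrigation {self.irrigation!r}")
        if self.tillage not in TILLAGE_PATTERNS:
            raise ValueError(f"unknown tillage {self.tillage!r}")
        if self.fert_application not in FERT_APPLICATIONS:
            raise ValueError(f"unknown fert_application {self.fert_application!r}")


class ControlFactors(NamedTuple):
    cf_n: float
    cf_c: float
    cf_ap: float
    cf_i: float
    climate_row_matched: bool = True


class HazardClass(NamedTuple):
    level: int
    label: str
    out_of_table: bool = False


@dataclass(frozen=True)
class HazardScore:
    """IPNOA factor scores, the hazard-index product and its class.

    ``hi`` is the product rounded to 2 decimals for reporting;
    ``hi_exact`` is the unrounded product (equal to the factor product
    to machine precision).
    """

    hf_f: int
    hf_m: int
    hf_s: int
    cf_n: float
    cf_c: float
    cf_ap: float
    cf_i: float
    hi: float
    hi_exact: float
    level: int
    label: str

    @property
    def hazard_sum(self) -> int:
        return self.hf_f + self.hf_m + self.hf_s


@dataclass(frozen=True)
class SewerZone:
    """One sewer zone of the IPNOC nitrogen-leakage estimate.

    ``n_load`` (kg/year of nitrogen in transit) may be given directly or
    derived as inhabitants * per_capita_n * infiltration.
    """

    pipe_length: float
    pipe_age: float
    pipe_life: float
    base_leakage: float  # percent of the transiting load over the pipe lifetime
    inhabitants: int = 0
    per_capita_n: float = 0.0
    infiltration: float = 0.0
    n_load: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pipe_age < 0:
            raise ValueError("pipe_age must be >= 0")
        if self.pipe_life <= 0:
            raise ValueError("pipe_life must be > 0")
        if not 0 <= self.base_leakage <= 100:
            raise ValueError("base_leakage is a percentage in [0, 100]")
        if not 0 <= self.infiltration <= 1:
            raise ValueError("infiltration is a fraction in [0, 1]")

    @property
    def nitrogen_load(self) -> float:
        if self.n_load is not None:
            return self.n_load
        return self.inhabitants * self.per_capita_n * self.infiltration


class IpnocResult(NamedTuple):
    ny_literal: float  # kg*m/year, the sum evaluated literally
    ny_per_metre: float  # kg/year, literal sum over total pipe length
    total_length: float


def _midpoint(amount: float | tuple[float, float] | Sequence[float]) -> float:
    if isinstance(amount, (tuple, list)):
        lo, hi = float(amount[0]), float(amount[1])
        return 0.5 * (lo + hi)
    return float(amount)


def score_hazard_factor(
    amount: float | tuple[float, float],
    kind: str,
    absent_as_zero: bool = True,
) -> int:
    """Band score (0-5) of a fertilization rate.

    ``absent_as_zero=True`` (default) lets a zero application rate
    contribute 0 to the hazard sum — the behaviour under which the
    published per-land-use indices are internally consistent.
    ``absent_as_zero=False`` follows the score table literally, where a
    zero rate scores 1. A (lo, hi) range is scored at its midpoint.
    """
    if kind not in FERT_KINDS:
        raise ValueError(f"unknown fertilization kind {kind!r}")
    a = _midpoint(amount)
    if a < 0:
        raise ValueError("amount must be >= 0 kg/ha")
    tab = load_score_tables()["hazard_factors"][kind]
    if a == 0:
        return 0 if absent_as_zero else int(tab["zero"])
    for edge, score in zip(tab["edges"], tab["scores"]):
        if a <= edge:
            return int(score)
    return int(tab["above"])


def _score_soil_n(soil_n: float) -> float:
    # band edges are exclusive upper bounds except the top of the 1.02
    # band (the highest class is "> 0.5", so 0.5 itself scores 1.02)
    rows = load_score_tables()["control_factors"]["soil_n"]
    for i, row in enumerate(rows):
        upto = row["upto"]
        if upto is None:
            return float(row["score"])
        last_closed = i == len(rows) - 2
        if soil_n < upto or (last_closed and soil_n == upto):
            return float(row["score"])
    raise AssertionError("soil_n table is total by construction")


def _score_climate(rainfall: float, temperature: float) -> tuple[float, bool]:
    """Climate control factor from the rainfall/temperature row table.

    Rows are evaluated in printed order; the first whose rainfall AND
    temperature bands both match wins. If no row matches both, the first
    row matching rainfall alone is used; failing that, the row with the
    nearest rainfall band. Returns (score, matched_exactly).
    """
    rows = load_score_tables()["control_factors"]["climate"]

    def in_band(v: float, band: list) -> bool:
        lo, hi = band
        return (lo is None or v >= lo) and (hi is None or v <= hi)

    for row in rows:
        if in_band(rainfall, row["rain"]) and in_band(temperature, row["temp"]):
            return float(row["score"]), True
    for row in rows:
        if in_band(rainfall, row["rain"]):
            return float(row["score"]), False

    def band_dist(v: float, band: list) -> float:
        lo, hi = band
        lo = -math.inf if lo is None else lo
        hi = math.inf if hi is None else hi
        return max(lo - v, v - hi, 0.0)

    best = min(rows, key=lambda r: band_dist(rainfall, r["rain"]))
    return float(best["score"]), False


def score_control_factors(
    inputs: IpnoaInputs, ap_combine: str = "fertilization"
) -> ControlFactors:
    """The four IPNOA control factors for one input set.

    ``ap_combine`` selects how the agronomic-practice factor CF_ap is
    formed from the interleaved tillage / fertilization-type column:
    "fertilization" (default) takes the fertilization-type score, except
    that no-tillage takes its own 0.94 row; "product" multiplies the
    tillage and fertilization-type scores (exploratory alternative).
    """
    tabs = load_score_tables()["control_factors"]
    cf_n = _score_soil_n(inputs.soil_n)
    cf_c, matched = _score_climate(inputs.rainfall, inputs.temperature)
    cf_i = float(tabs["irrigation"][inputs.irrigation])
    fert_score = float(tabs["fert_application"][inputs.fert_application])
    till_score = float(tabs["tillage"][inputs.tillage])
    if ap_combine == "fertilization":
        cf_ap = till_score if inputs.tillage == "no_tillage" else fert_score
    elif ap_combine == "product":
        cf_ap = till_score * fert_score
    else:
        raise ValueError(f"unknown ap_combine {ap_combine!r}")
    return ControlFactors(cf_n, cf_c, cf_ap, cf_i, matched)


def classify_hi(hi: float, bands: str = "strict") -> HazardClass:
    """Classify a hazard index into its six-level band.

    Values below the lowest band clamp to level 1 and above the highest
    to level 6, both flagged ``out_of_table``. A value falling in one of
    the small gaps between consecutive printed bands takes the lower
    band's level. ``bands="paper_compat"`` selects the reverse-
    engineered variant table (see the packaged YAML).
    """
    if hi <= 0:
        raise ValueError("hazard index must be > 0")
    table = load_score_tables()["classification"][bands]
    lo0 = table[0][0]
    if hi < lo0:
        return HazardClass(int(table[0][2]), str(table[0][3]), True)
    prev = table[0]
    for row in table:
        lo, up, level, label = row
        if lo <= hi <= up:
            return HazardClass(int(level), str(label), False)
        if hi < lo:  # in the gap below this band: lower band's level
            return HazardClass(int(prev[2]), str(prev[3]), False)
        prev = row
    last = table[-1]
    return HazardClass(int(last[2]), str(last[3]), True)


def ipnoa_hi(
    hf_f: int,
    hf_m: int,
    hf_s: int,
    cf_n: float,
    cf_c: float,
    cf_ap: float,
    cf_i: float,
    bands: str = "strict",
) -> HazardScore:
    """Assemble the IPNOA hazard index from factor scores.

    HI = (HF_f + HF_m + HF_s) * CF_n * CF_c * CF_ap * CF_i, reported to
    2 decimals and classified against the band table.
    """
    for name, v in (("hf_f", hf_f), ("hf_m", hf_m), ("hf_s", hf_s)):
        if not 0 <= v <= 5:
            raise ValueError(f"{name} must be an integer score in 0..5")
    for name, v in (("cf_n", cf_n), ("cf_c", cf_c), ("cf_ap", cf_ap), ("cf_i", cf_i)):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    exact = (hf_f + hf_m + hf_s) * cf_n * cf_c * cf_ap * cf_i
    cls = classify_hi(exact, bands=bands) if exact > 0 else HazardClass(1, "Unlikely", True)
    return HazardScore(
        hf_f=hf_f,
        hf_m=hf_m,
        hf_s=hf_s,
        cf_n=cf_n,
        cf_c=cf_c,
        cf_ap=cf_ap,
        cf_i=cf_i,
        hi=round(exact, 2),
        hi_exact=exact,
        level=cls.level,
        label=cls.label,
    )


def score_ipnoa(
    inputs: IpnoaInputs,
    absent_as_zero: bool = True,
    ap_combine: str = "fertilization",
    bands: str = "strict",
) -> HazardScore:
    """End-to-end IPNOA scoring from raw inputs to classified index."""
    hf_f = score_hazard_factor(inputs.inorganic_fert, "inorganic", absent_as_zero)
    hf_m = score_hazard_factor(inputs.organic_fert, "organic", absent_as_zero)
    hf_s = score_hazard_factor(inputs.sludge, "sludge", absent_as_zero)
    cf = score_control_factors(inputs, ap_combine=ap_combine)
    return ipnoa_hi(hf_f, hf_m, hf_s, cf.cf_n, cf.cf_c, cf.cf_ap, cf.cf_i, bands=bands)


def ipnoc_lc(base_leakage: float, age: float, life: float) -> float:
    """Age-adjusted leakage fraction L_c = L_e * age/life.

    ``base_leakage`` is the lifetime leakage percentage of the pipe
    material; the return value is a fraction. Ages beyond the design
    life are allowed (L_c then exceeds the base fraction).
    """
    if life <= 0:
        raise ValueError("pipe life must be > 0")
    if age < 0:
        raise ValueError("pipe age must be >= 0")
    return (base_leakage / 100.0) * (age / life)


def ipnoc_ny(zones: Sequence[SewerZone]) -> IpnocResult:
    """Annual nitrogen leaking from the sewer network.

    The literal sum N_y = sum(L_c * N_i * L_i) carries units kg*m/year;
    the normalized variant divides by the total pipe length, giving a
    mean leaked load in kg/year.
    """
    if len(zones) == 0:
        raise ValueError("need at least one sewer zone")
    literal = 0.0
    total_len = 0.0
    for z in zones:
        lc = ipnoc_lc(z.base_leakage, z.pipe_age, z.pipe_life)
        literal += lc * z.nitrogen_load * z.pipe_length
        total_len += z.pipe_length
    per_metre = literal / total_len if total_len > 0 else float("nan")
    return IpnocResult(literal, per_metre, total_len)


def classify_ipnoc(value: float, breakpoints: Sequence[tuple[float, int, str]]) -> HazardClass:
    """Classify an IPNOC estimate against a user-supplied breakpoint table.

    ``breakpoints`` is a sequence of (upper_edge, level, label) rows in
    ascending order; no default table is provided because none is
    established.
    """
    if not breakpoints:
        raise ValueError("a breakpoint table is required (no default exists)")
    for upper, level, label in breakpoints:
        if value <= upper:
            return HazardClass(int(level), str(label), False)
    _, level, label = breakpoints[-1]
    return HazardClass(int(level), str(label), True)


def read_sewer_zones_csv(path: str | Path) -> list[SewerZone]:
    """Read sewer zones from CSV (one row per zone, SewerZone field names)."""
    df = pd.read_csv(path)
    needed = ["pipe_length", "pipe_age", "pipe_life", "base_leakage"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    zones = []
    for r in df.to_dict("records"):
        zones.append(
            SewerZone(
                pipe_length=float(r["pipe_length"]),
                pipe_age=float(r["pipe_age"]),
                pipe_life=float(r["pipe_life"]),
                base_leakage=float(r["base_leakage"]),
                inhabitants=int(r.get("inhabitants", 0) or 0),
                per_capita_n=float(r.get("per_capita_n", 0.0) or 0.0),
                infiltration=float(r.get("infiltration", 0.0) or 0.0),
                n_load=float(r["n_load"]) if "n_load" in r and pd.notna(r["n_load"]) else None,
            )
        )
    return zones


def write_hazard_report(scores: dict[str, HazardScore], path: str | Path) -> None:
    """Write per-land-use IPNOA scores as a CSV report."""
    df = pd.DataFrame(
        [
            {
                "land_use": lu,
                "hf_f": s.hf_f,
                "hf_m": s.hf_m,
                "hf_s": s.hf_s,
                "cf_n": s.cf_n,
                "cf_c": s.cf_c,
                "cf_ap": s.cf_ap,
                "cf_i": s.cf_i,
                "hi": f"{s.hi:.2f}",
                "level": s.level,
                "label": s.label,
            }
            for lu, s in scores.items()
        ]
    )
    df.to_csv(path, index=False)
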