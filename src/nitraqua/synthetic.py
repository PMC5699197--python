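"""Synthetic well-survey generator with the statistical structure the
analysis assumes.

Wells are scattered uniformly over a flat rectangular plain; nitrate is
a land-use mean plus one draw of a zero-mean Gaussian random field
(covariance taken from a generating semivariogram) plus iid measurement
noise, truncated at zero. Land-use labels are assigned in contiguous
spatial blocks so the class means create spatial patterning, and the
climate label splits the plain along the y axis. Every output is a pure
function of the spec including its seed: a single root seed fans out to
per-component substreams, so adding one generator call does not perturb
earlier draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.spatial.distance import cdist

from .data_model import LAND_USES, SampleTable, WellSample
from .hazard import IpnoaInputs, SewerZone
from .interpolation import VariogramModel
from .qaqc import Triplicate


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of the synthetic well generator.

    ``landuse_means`` are mg/L class levels; ``landuse_props`` must sum
    to 1; ``climate_split`` is the fraction of wells labelled semi-arid
    (assigned to the northern part of the extent); ``noise_sd`` is the
    iid measurement-noise standard deviation in mg/L.
    """

    n_wells: int
    extent: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax (m)
    variogram: VariogramModel
    landuse_means: Mapping[str, float]
    landuse_props: Mapping[str, float]
    climate_split: float
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_wells < 4:
            raise ValueError("n_wells must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.climate_split <= 1:
            raise ValueError("climate_split is a fraction")
        if abs(sum(self.landuse_props.values()) - 1.0) > 1e-9:
            raise ValueError("landuse_props must sum to 1")
        if set(self.landuse_props) - set(LAND_USES):
            raise ValueError("landuse_props has unknown land-use labels")
        xmin, xmax, ymin, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("extent must have positive width and height")


def simulate_gaussian_field(
    locations: np.ndarray, variogram: VariogramModel, seed: int | np.random.Generator
) -> np.ndarray:
    """One draw of a zero-mean Gaussian random field at given locations.

    The covariance is C(h) = partial_sill * rho(h) off-diagonal with the
    nugget added on the diagonal only (the nugget is spatially
    uncorrelated by definition). Factorized by Cholesky with a small
    jitter ladder; a covariance that stays non-PSD is signalled.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    xy = np.asarray(locations, dtype=float)
    n = len(xy)
    d = cdist(xy, xy)
    if n > 1 and np.any(d[~np.eye(n, dtype=bool)] < 1e-12):
        raise ValueError("locations must be distinct")
    if variogram.sill == 0.0:
        return np.zeros(n)
    cov = variogram.partial_sill * variogram.correlation(d)
    cov[np.diag_indices(n)] += variogram.nugget
    for jitter in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            L = np.linalg.cholesky(cov + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            continue
    else:
        raise ValueError("covariance matrix is not positive semi-definite")
    return L @ rng.standard_normal(n)


def _largest_remainder_counts(n: int, props: Sequence[float]) -> list[int]:
    """Integer class counts summing to n, matching proportions within 1."""
    raw = [n * p for p in props]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = np.argsort([c - r for c, r in zip(counts, raw)], kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    return counts


def generate_well_table(spec: FieldSpec) -> tuple[SampleTable, np.ndarray]:
    """Generate a well table and the noiseless truth at the wells.

    Returns (samples, truth) where ``truth`` is the land-use mean plus
    the random-field draw (no measurement noise, no truncation), aligned
    with the samples. Negative noisy concentrations are truncated to 0.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_loc, rng_field, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    xmin, xmax, ymin, ymax = spec.extent
    n = spec.n_wells
    xy = np.column_stack(
        [rng_loc.uniform(xmin, xmax, n), rng_loc.uniform(ymin, ymax, n)]
    )

    # land use in contiguous west-to-east blocks matching the proportions
    land_use = np.empty(n, dtype=object)
    classes = list(spec.landuse_props)
    counts = _largest_remainder_counts(n, [spec.landuse_props[c] for c in classes])
    order_x = np.argsort(xy[:, 0], kind="stable")
    start = 0
    for cls, cnt in zip(classes, counts):
        land_use[order_x[start: start + cnt]] = cls
        start += cnt

    # semi-arid fraction assigned to the northern block
    climate = np.full(n, "arid", dtype=object)
    n_semi = int(round(spec.climate_split * n))
    order_y = np.argsort(xy[:, 1], kind="stable")
    if n_semi > 0:
        climate[order_y[-n_semi:]] = "semi_arid"

    grf = simulate_gaussian_field(xy, spec.variogram, rng_field)
    means = np.array([spec.landuse_means[lu] for lu in land_use], dtype=float)
    truth = means + grf
    noisy = truth + rng_noise.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else truth.copy()
    nitrate = np.maximum(noisy, 0.0)

    samples = [
        WellSample(
            well_id=f"W{i + 1:03d}",
            x=float(xy[i, 0]),
            y=float(xy[i, 1]),
            elev=300.0,
            climate=str(climate[i]),
            land_use=str(land_use[i]),
            season="spring",
            nitrate=float(nitrate[i]),
        )
        for i in range(n)
    ]
    return SampleTable(tuple(samples)), truth


def generate_triplicates(
    true_values: Sequence[float], cv: float, bias: float, seed: int
) -> list[Triplicate]:
    """Triplicate QA measurements around certified reference values.

    Replicates ~ Normal(true*(1+bias), (cv*true)^2), floored at 0. With
    cv=0 and bias=0 the recovery is exactly 100%.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for tv in true_values:
        reps = rng.normal(tv * (1.0 + bias), cv * tv, 3)
        reps = np.maximum(reps, 0.0)
        out.append(Triplicate(float(tv), (float(reps[0]), float(reps[1]), float(reps[2]))))
    return out


@dataclass(frozen=True)
class Scenario:
    """A packaged study scenario: generator spec, per-land-use IPNOA
    inputs and the sewer zone of the IPNOC estimate."""

    field_spec: FieldSpec
    ipnoa_inputs: dict[str, IpnoaInputs]
    sewer_zone: SewerZone
    qa_reference_values: tuple[float, ...]


def scenario_qazvin_like() -> Scenario:
    """The packaged semi-arid plain scenario.

    Carries the study-design parameters of a 162-well survey over a
    flat plain with two climate zones and four land uses, the
    reconstructed per-land-use fertilization/control inputs, and the
    printed sewer-zone parameters of the civil-source estimate. Loaded
    from the packaged ``qazvin_scenario.yaml``.
    """
    text = resources.files("nitraqua.config").joinpath("qazvin_scenario.yaml").read_text()
    cfg = yaml.safe_load(text)

    f = cfg["field"]
    vg = f["variogram"]
    spec = FieldSpec(
        n_wells=int(f["n_wells"]),
        extent=tuple(float(v) for v in f["extent"]),  # type: ignore[arg-type]
        variogram=VariogramModel(
            kind=vg["kind"],
            nugget=float(vg["nugget"]),
            partial_sill=float(vg["partial_sill"]),
            range_m=float(vg["range_m"]),
        ),
        landuse_means={k: float(v) for k, v in f["landuse_means"].items()},
        landuse_props={k: float(v) for k, v in f["landuse_props"].items()},
        climate_split=float(f["climate_split"]),
        noise_sd=float(f["noise_sd"]),
        seed=int(f["seed"]),
    )

    shared = cfg["ipnoa"]["shared"]
    inputs: dict[str, IpnoaInputs] = {}
    for lu in LAND_USES:
        row = cfg["ipnoa"][lu]

        def _amt(v):  # scalar or [lo, hi] range
            return tuple(float(x) for x in v) if isinstance(v, list) else float(v)

        inputs[lu] = IpnoaInputs(
            inorganic_fert=_amt(row["inorganic"]),
            organic_fert=_amt(row["organic"]),
            sludge=_amt(row["sludge"]),
            soil_n=float(shared["soil_n"]),
            irrigation=str(shared["irrigation"]),
            rainfall=float(shared["rainfall"]),
            temperature=float(shared["temperature"]),
            tillage=str(shared["tillage"]),
            fert_application=str(shared["fert_application"]),
        )

    z = cfg["sewer_zone"]
    zone = SewerZone(
        pipe_length=float(z["pipe_length_m"]),
        pipe_age=float(z["pipe_age_years"]),
        pipe_life=float(z["pipe_life_years"]),
        base_leakage=float(z["base_leakage_pct"]),
        inhabitants=int(z["inhabitants"]),
        per_capita_n=float(z["per_capita_n_kg"]),
        infiltration=float(z["infiltration"]),
    )
    return Scenario(
        field_spec=spec,
        ipnoa_inputs=inputs,
        sewer_zone=zone,
        qa_reference_values=tuple(float(v) for v in cfg["qa_reference_values"]),
    )
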