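# nitraqua

Spatial analysis of nitrate in groundwater: QA/QC of laboratory
measurements, comparison of spatial interpolation methods by
cross-validated error, and parametric aquifer-vulnerability scoring with
the IPNOA (agricultural) and IPNOC (sewer-leakage) hazard indices.

The package is aimed at environmental-health and hydrogeology
practitioners who monitor wells over a plain aquifer and need to
(1) check that their nitrate measurements meet precision/accuracy
objectives, (2) pick a defensible interpolation method for mapping, and
(3) screen the aquifer's vulnerability to agricultural and civil
nitrogen sources.

## What it computes

**Interpolation.** Four point interpolators over planar (metre)
coordinates, implemented from first principles:

- ordinary kriging — weights solve [[Γ, 1],[1ᵀ, 0]]·[w, μ] = [γ₀, 1]
  from a semivariogram γ(h) fitted by weighted least squares
  (spherical/exponential/gaussian), so Σwᵢ = 1;
- inverse-distance weighting, wᵢ ∝ dᵢ^(−π) (default π = 2);
- thin-plate spline, z(x) = a₀ + a₁x + a₂y + Σλⱼ·rⱼ²log rⱼ, the exact
  minimum-curvature interpolant;
- Sibson natural neighbour — the weight of each sample is the Voronoi
  area its cell cedes to the inserted target, undefined (nodata)
  outside the convex hull.

Methods are compared by leave-one-out cross-validation with
RMSE = √(Σ(ẑᵢ−zᵢ)²/n), %RMSE = RMSE/z̄, and MRE = (1/n)Σ|(ẑᵢ−zᵢ)/zᵢ|.

**Hazard indices.** IPNOA combines additive hazard factors (band scores
of mineral fertilizer, manure and sludge application rates) with
multiplicative control factors (soil N, climate, agronomic practice,
irrigation):

    HI = (HF_f + HF_m + HF_s) · CF_n · CF_c · CF_ap · CF_i

classified into six levels from "Unlikely" to "Very high". IPNOC
estimates annual nitrogen leaked from sewers, N_y = Σ L_c·N_i·L_i with
the age-adjusted leakage fraction L_c = L_e·(age/life).

**QA/QC.** Triplicate precision (RSD = sd/mean), recovery of certified
reference samples (with the 85–115% acceptance window), detection-limit
checks, Welch t and one-way ANOVA group comparisons, and the
calculated-fixed-radius wellhead protection zone r = √(Q·t/(π·n·H)).

A synthetic-data module generates well surveys with known geostatistical
structure (Gaussian random field + land-use means + measurement noise)
so every stage is testable without field data; `scenario_qazvin_like()`
packages a complete semi-arid plain study design.

## Worked example

```
$ nitraqua simulate --out wells.csv
wrote 162 wells to wells.csv

$ nitraqua crossval wells.csv
             idw: MRE=1.3932 RMSE=12.0667 %RMSE=0.4566 (n=162)
         kriging: MRE=0.8930 RMSE=10.3254 %RMSE=0.3907 (n=162)
natural_neighbor: MRE=0.8788 RMSE=11.2507 %RMSE=0.4253 (n=151)
          spline: MRE=0.9429 RMSE=11.5310 %RMSE=0.4363 (n=162)
ranking by rmse: kriging, natural_neighbor, spline, idw
```

Each line is one interpolator's leave-one-out score over the 162
synthetic wells: kriging predicts held-out wells with an RMSE of
10.3 mg/L (39% of the mean concentration); natural neighbour has the
lowest mean relative error but can only evaluate 151 wells because the
11 hull wells fall outside the reduced convex hull of their folds.

```
$ nitraqua hazard
agricultural: HF=(3,3,0) CF=(0.96,0.98,1.04,1.04) HI=6.11 level=3 (Low)
      steppe: HF=(3,0,0) CF=(0.96,0.98,1.04,1.04) HI=3.05 level=1 (Unlikely)
 residential: HF=(3,0,0) CF=(0.96,0.98,1.04,1.04) HI=3.05 level=1 (Unlikely)
       mixed: HF=(3,2,0) CF=(0.96,0.98,1.04,1.04) HI=5.09 level=2 (Very low)
IPNOC: Ny=1420518.9 kg.m/yr (852.37 kg/yr per metre-normalized, L=1666.6 m)
```

Agricultural land scores highest: mineral fertilizer at 70–120 kg/ha
and manure each contribute a hazard score of 3, and the product with
the four control factors gives HI = 6.11, hazard level 3 ("Low").
The IPNOC line is the annual nitrogen leak from the scenario's sewer
zone (7% lifetime leakage, 5 of 15 years of age, 9812 inhabitants at
4.38 kg N/capita·yr with 85% infiltration over 1.67 km of pipe).

The full pipeline (QA/QC → statistics → cross-validation → best-method
raster → hazard reports) runs from one TOML config:

```
$ nitraqua run config.toml
```

writing `cv_report.csv`, `descriptive_stats.csv`, `hazard_ipnoa.csv`,
an ESRI ASCII surface for the best-ranked method, and a JSON summary —
all byte-reproducible for a fixed config and seed.

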