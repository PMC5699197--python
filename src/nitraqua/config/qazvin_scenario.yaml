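# Packaged study scenario: a ~162-well nitrate survey over a flat
# semi-arid plain, with the published per-land-use fertilization and
# control-factor inputs and the sewer-zone parameters of the civil
# (IPNOC) estimate.
#
# The generating variogram, noise level and default seed were calibrated
# once so the default draw spans the observed concentration range
# (~5-77 mg/L) around the per-land-use mean levels; see docs/methods.md.
field:
  n_wells: 162
  extent: [0.0, 60000.0, 0.0, 40000.0] # metres
  variogram: {kind: spherical, nugget: 20.0, partial_sill: 240.0, range_m: 12000.0}
  landuse_means:
    agricultural: 22.45
    steppe: 21.05
    residential: 26.58
    mixed: 29.43
  landuse_props:
    agricultural: 0.41
    steppe: 0.17
    residential: 0.18
    mixed: 0.24
  climate_split: 0.747 # fraction of wells in the (northern) semi-arid zone
  noise_sd: 2.0 # mg/L measurement noise
  seed: 42

# Certified reference concentrations (mg/L) of the QA triplicate design.
qa_reference_values: [5.0, 25.0, 50.0]

ipnoa:
  # Shared site conditions: low-nitrogen saline soils, an arid plain
  # average rainfall of 141 mm/yr at 13 degC (no climate row matches;
  # the nearest rainfall band <600 mm applies), border irrigation and
  # traditional tillage with fertirrigation.
  shared:
    soil_n: 0.05 # % N, "< 0.1" band
    rainfall: 141 # mm/year, plain average
    temperature: 13 # deg C
    irrigation: border
    tillage: traditional
    fert_application: fertirrigation
  # Fertilization rates (kg/ha); [lo, hi] ranges score at the midpoint.
  # Organic rates per land use are reconstructed from the published
  # factor scores (no rate is printed); sludge is not applied anywhere.
  agricultural: {inorganic: [70, 120], organic: 200, sludge: 0}
  mixed: {inorganic: [70, 120], organic: 75, sludge: 0}
  steppe: {inorganic: [70, 120], organic: 0, sludge: 0}
  residential: {inorganic: [70, 120], organic: 0, sludge: 0}

sewer_zone:
  pipe_material: concrete
  pipe_length_m: 1666.555 # 21.23 m/ha over 78.5 ha
  pipe_age_years: 5
  pipe_life_years: 15
  base_leakage_pct: 7
  inhabitants: 9812
  per_capita_n_kg: 4.38 # kg N per capita per year
  infiltration: 0.85
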