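# IPNOA score tables: hazard-factor fertilization bands (kg/ha of N) and
# multiplicative control factors. Regional recalibrations can edit this
# file without code changes.
#
# Hazard factors: a zero application rate scores 1 in the published
# table ("absent" handling is an option of the scoring function); the
# bands below are upper edges, inclusive, applied above zero.
hazard_factors:
  inorganic: {edges: [25, 100, 180], scores: [2, 3, 4], above: 5, zero: 1}
  organic: {edges: [150, 300, 500], scores: [2, 3, 4], above: 5, zero: 1}
  sludge: {edges: [150, 500, 1500], scores: [2, 3, 4], above: 5, zero: 1}

control_factors:
  # soil nitrogen content (%): upper band edges, inclusive; null = open
  soil_n:
    - {upto: 0.1, score: 0.96}
    - {upto: 0.15, score: 0.98}
    - {upto: 0.22, score: 1.00}
    - {upto: 0.5, score: 1.02}
    - {upto: null, score: 1.04}
  irrigation: {basin: 1.06, border: 1.04, sprinkler: 1.02, none: 1.00}
  # climate rows in printed order: first row whose rainfall (mm/yr) AND
  # temperature (deg C) bands both match wins; null bound = open
  climate:
    - {rain: [1200, null], temp: [6, 15], score: 1.01}
    - {rain: [1050, 1150], temp: [13, 13], score: 1.08}
    - {rain: [950, 1100], temp: [14, 16], score: 1.06}
    - {rain: [800, 1000], temp: [12, 12], score: 1.04}
    - {rain: [600, 1000], temp: [15, 16], score: 1.02}
    - {rain: [600, 800], temp: [12, 13], score: 1.00}
    - {rain: [null, 600], temp: [15, 30], score: 0.98}
  fert_application:
    {fertirrigation: 1.04, total_surface: 1.00, through_leaves: 0.98, localized: 0.96}
  tillage: {traditional: 1.04, minimum: 0.96, no_tillage: 0.94}

# Hazard-index classification bands: [lower, upper, level, label].
# "strict" is the published band table verbatim (note the small gaps
# between consecutive bands; values falling in a gap take the lower
# band's level). "paper_compat" is a synthetic, reverse-engineered
# variant whose class-2 lower edge is dropped to 3.05 so that the
# published per-land-use classifications are reproduced; it is provided
# for comparison only and asserted nowhere.
classification:
  strict:
    - [2.54, 3.18, 1, Unlikely]
    - [3.19, 5.88, 2, Very low]
    - [5.89, 7.42, 3, Low]
    - [7.43, 9.31, 4, Moderate]
    - [9.32, 11.10, 5, High]
    - [11.11, 17.66, 6, Very high]
  paper_compat:
    - [2.54, 3.04, 1, Unlikely]
    - [3.05, 5.88, 2, Very low]
    - [5.89, 7.42, 3, Low]
    - [7.43, 9.31, 4, Moderate]
    - [9.32, 11.10, 5, High]
    - [11.11, 17.66, 6, Very high]
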