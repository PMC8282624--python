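# Demo run: 60x60 synthetic Central-America-like landscape, two functional
# types (wet-like and dry-like, 4 species each), four warming/drying
# scenarios (2 RCP-like intensities x 2 GCM-like variants).
# Desk-scale modelling settings (replicates, pseudo-absence counts) keep the
# full pipeline under a few minutes on one CPU.
seed: 42

grid:
  n_rows: 60
  n_cols: 60
  lat_min: 4.0
  lat_max: 24.0
  lon_min: -100.0
  lon_max: -68.0

landscape:
  lapse_rate: 0.0065
  autocorrelation_length: 5.0
  elevation_relief: 1500.0
  sea_level_temp: 27.0
  temp_noise: 1.0
  precip_base: 2200.0
  precip_lat_gradient: -50.0
  precip_noise: 350.0

species:
  wet_a: {optima: {temperature: 25.5, precipitation: 2250}, breadths: {temperature: 3.0, precipitation: 320}, max_prob: 0.9, n_records: 800}
  wet_b: {optima: {temperature: 25.0, precipitation: 2150}, breadths: {temperature: 3.0, precipitation: 300}, max_prob: 0.9, n_records: 800}
  wet_c: {optima: {temperature: 26.0, precipitation: 2300}, breadths: {temperature: 3.5, precipitation: 340}, max_prob: 0.9, n_records: 800}
  wet_d: {optima: {temperature: 24.5, precipitation: 2100}, breadths: {temperature: 3.0, precipitation: 310}, max_prob: 0.9, n_records: 800}
  dry_a: {optima: {temperature: 25.5, precipitation: 1250}, breadths: {temperature: 3.0, precipitation: 320}, max_prob: 0.9, n_records: 800}
  dry_b: {optima: {temperature: 25.0, precipitation: 1350}, breadths: {temperature: 3.0, precipitation: 300}, max_prob: 0.9, n_records: 800}
  dry_c: {optima: {temperature: 26.0, precipitation: 1200}, breadths: {temperature: 3.5, precipitation: 340}, max_prob: 0.9, n_records: 800}
  dry_d: {optima: {temperature: 24.5, precipitation: 1400}, breadths: {temperature: 3.0, precipitation: 310}, max_prob: 0.9, n_records: 800}

pfts:
  wet_like: [wet_a, wet_b, wet_c, wet_d]
  dry_like: [dry_a, dry_b, dry_c, dry_d]

scenarios:
  - {label: rcp45_gcmA, rcp: rcp45, gcm: gcmA, offsets: {temperature: 1.5}, factors: {precipitation: 0.85}}
  - {label: rcp45_gcmB, rcp: rcp45, gcm: gcmB, offsets: {temperature: 1.8}, factors: {precipitation: 0.82}}
  - {label: rcp85_gcmA, rcp: rcp85, gcm: gcmA, offsets: {temperature: 3.0}, factors: {precipitation: 0.70}}
  - {label: rcp85_gcmB, rcp: rcp85, gcm: gcmB, offsets: {temperature: 3.4}, factors: {precipitation: 0.68}}

learners:
  - {name: gam, pa_strategy: random, pa_count: 3000}
  - {name: mars, pa_strategy: random, pa_count: 3000}
  - {name: maxent, pa_strategy: random, pa_count: 3000, presence_only: true}
  - {name: rf, pa_strategy: disk, pa_count: equal, hyperparams: {d_min: 2.0}}

thresholds:
  vif: 10.0
  filter: 0.7
  min_agree: 3
  presence_min: 2
  quantile: 0.05
  min_records: 200

modelling:
  n_replicates: 12
  k_projection: 6
  anova_cells: 120
  n_background_vif: 2000
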