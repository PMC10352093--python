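# Full-pipeline configuration for a synthetic reserve survey.
# Stages read only the sections they need; every stage accepts
# --seed / --out overrides on the command line.

seed: 1
out_dir: runs/demo
pixel_area_km2: 0.5

# synthetic survey (used by `secrsearch simulate`); to analyse real data,
# delete this block and add:
# inputs:
#   boundary: path/to/boundary.geojson
#   tracks: path/to/tracks.csv        # date,time,lon,lat
#   sightings: path/to/sightings.csv  # date,lon,lat,individual_id,sex,age_class,id_quality
scenario:
  area_km2: 150.0
  n_days: 25
  km_per_day: 80.0
  N_true: 40
  prop_male_true: 0.5
  lambda0_true: 0.01
  beta_eff_true: 0.79
  sigma_f_true: 2.0
  sigma_m_true: 3.0
  point_spacing_km: 0.2

sampler:
  n_iter: 3000        # full-survey analyses use 31000 / 1000 / 4 chains / M=200
  burn_in: 1000
  n_chains: 3
  M: 100
  latent_every: 10

models: [1, 2, 3, 4, 5]
gof_n_rep: 100

rarefaction:
  increments_km: [400, 800, 1200, 1600]
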