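# Demo configuration: a 16x16 landscape with 12 species, completing in
# seconds on one CPU.  Every downstream default appears here exactly once.
out_dir: runs/demo
nrows: 16
ncols: 16
n_continuous: 4
n_categorical: 1
correlation_length: 4.0
n_codes: 5
nodata_fraction: 0.0
cellsize: 500.0
n_species: 12
n_sites: 200
class_thresholds: [0.1, 0.5]
detection: proportional
n_continuous_traits: 3
trait_sigma2: 0.3
trait_root_state: 0.0
trait_lognormal: true
missing_fraction: 0.15
log_transform: [SLA, CH, RD]
beta: 0.1
min_presences: 5
sdm_scale: logistic
weights: [0.01, 0.1, 1.0]
convention: normalized
allometric_mode: printed
k_regions: 5
n_init: 10
scenario:
  clim1: 0.5
seed: 1
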