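# Pipeline configuration for the synthetic reference dataset.
# Paths are relative to this file.  From the repository root:
#   stpanel simulate --seed 20240222 --out examples/data
#   stpanel run-all --config examples/config.yaml
schema_version: 1
paths:
  units: data/units.geojson
  panel: data/panel.csv
  out_dir: data/out
weights:
  scheme: queen
inference:
  alpha: 0.05
  n_perm: 999
  seed: 20240222
regression:
  kernel: gaussian
  models: [ols, gwr, twr, gtwr]
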