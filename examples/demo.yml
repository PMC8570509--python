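# Demo: a 36 x 36 synthetic landscape (30 m cells) with a hill, an incised
# valley and a closed basin, plus a 3-group plant community with planted
# indicator species. Run with:  geohab run examples/demo.yml --outdir demo_run
seed: 7
synthetic:
  dem:
    nrows: 36
    ncols: 36
    cellsize: 30.0
    base_slope: 0.8          # m per cell, dipping due south
    noise_sd: 0.5            # m of white surface noise
    features:
      - {kind: hill, center: [9, 9], amplitude: 120.0, width: 200.0}
      - {kind: valley, center: [24, 4], end: [24, 32], amplitude: 40.0,
         width: 120.0}
      - {kind: basin, center: [29, 28], amplitude: 30.0, width: 150.0}
  community:
    n_groups: 3
    sites_per_group: 8
    n_indicators_per_group: 2
    n_noise_species: 10
community:
  n_perm: 199
  alpha: 0.05
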