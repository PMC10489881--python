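# Simulate-mode pipeline run: paired-transect survey from the reference
# presets, cover estimation from painted quadrat images, trait
# derivation, and all twelve disturbance x elevation model fits.
mode: simulate
out_dir: run
seed: 1
chains: 3
iterations: 1500
warmup: 500
sim:
  seed: 1
  n_pairs: 14
  n_quadrats: 10
  elevation_range: [1580.0, 1980.0]
  max_per_quadrat: 5
  image_size: [64, 64]
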