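# Small end-to-end demo: 2 subject pairs, one cortical layer, two sites per
# layer, reduced 48x48x32 fields at the full voxel calibration.
# Run:  cb1rquant run --config configs/demo.yaml
out_dir: scratch/demo_out
seed: 7
geometry:
  nx: 48
  ny: 48
  nz: 32
  measured_thickness: 20.0
cohort:
  n_pairs: 2
  shrinkage_factor: 0.5
  seed: 7
sites_per_layer: 2
layers: [III]
filters:
  frame_low_px: 1
  frame_high_px: 47
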