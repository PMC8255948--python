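# Desk-scale comparison profile: 64x64 grid, reduced geometry and counts,
# so the full 4-method x 3-realization sweep finishes in minutes on one CPU.
n_rows: 64
n_cols: 64
pixel_size: 0.984375
n_angles: 60
n_radial: 96
n_tof: 5
timing_resolution_ps: 550.0
total_events: 200000.0
background_fraction: 0.4
methods: [mlaa, kernel, red-kernel, unet-kernel]
n_outer: 200
record_every: 25
report_iteration: 200
kernel_k: 50
kernel_sigma: 1.0
patch_side: 3
ae_epochs: 300
redcnn_width: 32
unet_channels: [16, 32, 48, 56]
unet_penultimate: 12
n_realizations: 3
master_seed: 0
output_dir: null
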