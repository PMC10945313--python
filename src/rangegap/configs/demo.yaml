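# Bundled demo study: a 50x50 landscape with 12 virtual taxa and 60 PAs.
# Completes end-to-end in well under five minutes on one CPU.
seed: 1
grid_shape: [50, 50]
n_vars: 6
autocorr_scale: 5.0
n_taxa: 12
n_pas: 60
n_randomizations: 999
forest_fraction: 0.8
out_dir: results/demo
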