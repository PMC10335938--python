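# Shipped wild-type configuration.
# k_act and p_bypass are the output of scripts/calibrate.py (grid search
# against the published wild-type activation schedule); rerun that script to
# regenerate them.

seeds = [1]

[locus]
genotype = "wild_type"

[sim]
bin_size = 2000
dt = 0.01
v = 1
load_rate = 3.0
w_active = 1.0
w_background = 0.0015
unload_prob = 0.001
p_stall = 1.0
p_bypass = 0.000135          # calibrated
p_stall_reverse = 0.2
p_bypass_reverse = 0.008
embedded_full_block = 1.0
max_extruders = 1500
alpha = 1.0
c0 = 0.1
seed = 0

[timer]
t_wnt = 72.0
anterior_activation_rate = 0.11552453009332421   # ln 2 / 6
k_act = 0.09               # calibrated
contact_window = 2.0
t_enh = 96.0
polycomb_factor = 1.0
dilution_half_life = 4.0
expression_scale = 1.0
enh_halfwindow_bins = 2
anchor_window_bins = 5

[output]
out_dir = "."
snapshot_every = 0.05
t_start = 48.0
t_end = 168.0
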