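# Demonstration run: synthetic bait-vs-probe screen, reduced sizes so the
# full pipeline finishes in well under a minute.
seed = 7
n_perm = 2000
alpha = 0.05
screen_alpha = 0.05
weight_exponent = 1
null_sharing = sample
mode = simulate
sim_n_genes = 260
sim_probes_per_gene = 1-3
sim_n_signatures = 20
sim_genes_per_signature = 10
sim_noise_sd = 0.25
sim_effect_size = 1.0
sim_n_control = 3
sim_n_treated = 2
sim_n_compounds = 10
sim_conditions_per_compound = 4
sim_mimetic_compounds = CPD_01, CPD_02
n_bait_samples = 4
bait_directions = SIG_01:+1, SIG_02:+1, SIG_03:+1, SIG_04:+1, SIG_05:+1, SIG_06:+1, SIG_07:-1, SIG_08:-1, SIG_09:-1, SIG_10:-1
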