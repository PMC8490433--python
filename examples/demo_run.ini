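# Demo pipeline run: three-analyte mixture sensed at one site.
# Classes differ in blockage amplitude and bound-state noise signature,
# so the frequency-split features separate them.

[run]
stages = simulate, idealize, kinetics, features, classify
seed = 7

[acquisition]
sampling_rate_hz = 25000
analog_corner_hz = 1000
analog_filter_order = 4
duration_s = 60

[scheme]
type = mixture
i_p_pA = 120

[class:quiet]
i_b_pA = 90
k_on_per_M_s = 1e4
k_off_per_s = 5
proportion = 0.34

[class:flicker]
i_b_pA = 80
k_on_per_M_s = 1e4
k_off_per_s = 5
proportion = 0.33
telegraph_amp_pA = 10
telegraph_rate_per_s = 50

[class:hiss]
i_b_pA = 80
k_on_per_M_s = 1e4
k_off_per_s = 5
proportion = 0.33
broadband_sd_pA = 6

[noise]
baseline_sd_pA = 2

[titration]
concentrations_molar = 3e-4, 6e-4, 1e-3

[detection]
nominal_delta_i_pA = -40
min_duration_s = 1.2e-4

[fitting]
dwell_method = mle

[classification]
cutoff_hz = 100
filter_order = 4
test_fraction = 0.3
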