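# Euploid (2N littermate control) layer-4 regular-spiking preset.
# Passive circuit (whole-cell membrane test)
label = euploid
cm_pF = 70.0
rm_specific_MOhm_per_pF = 4.6
ra_MOhm = 10.0
vrest_mV = -66.0
# Network (Up/Down state) kinetics; rate is events per second of recording
# (the alternative inverse-median-interval reading is NOT used here).
upstate_duration_median_s = 2.2
upstate_rate_median_Hz = 0.048
# Spontaneous synaptic activity (median instantaneous frequency, 1/interval)
epsc_freq_median_Hz = 16.2
ipsc_freq_median_Hz = 13.7
# Evoked thalamocortical latencies: per-trial jitter SD = SEM * sqrt(n)
epsc_latency_mean_ms = 4.1
epsc_latency_sd_ms = 0.6325
ipsc_latency_mean_ms = 4.6
ipsc_latency_sd_ms = 0.2
# Action-potential kinematics bundle
ap.rheobase_pA = 55.0
ap.amplitude_mV = 112.0
ap.ahp_mV = -12.0
ap.fwhm_ms = 1.32
ap.threshold_mV = -40.6
ap.sfa_ratio = 1.27
ap.max_rise_V_per_s = 231.0
ap.max_decay_V_per_s = -113.0
# Synaptic reversal potentials used to isolate components
reversal_exc_mV = 20.0
reversal_inh_mV = -45.0
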