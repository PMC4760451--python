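# Trisomic (Ts65Dn) layer-4 regular-spiking preset.
label = trisomic
cm_pF = 94.0
rm_specific_MOhm_per_pF = 2.6
ra_MOhm = 10.0
vrest_mV = -64.8
# Network (Up/Down state) kinetics; rate is events per second of recording
upstate_duration_median_s = 1.9
upstate_rate_median_Hz = 0.038
# Spontaneous synaptic activity (median instantaneous frequency, 1/interval)
epsc_freq_median_Hz = 8.7
ipsc_freq_median_Hz = 7.4
# Evoked thalamocortical latencies: per-trial jitter SD = SEM * sqrt(n)
epsc_latency_mean_ms = 4.6
epsc_latency_sd_ms = 0.3
ipsc_latency_mean_ms = 6.3
ipsc_latency_sd_ms = 0.4
# Action-potential kinematics bundle
ap.rheobase_pA = 73.0
ap.amplitude_mV = 115.0
ap.ahp_mV = -11.7
ap.fwhm_ms = 1.27
ap.threshold_mV = -38.9
ap.sfa_ratio = 1.29
ap.max_rise_V_per_s = 237.0
ap.max_decay_V_per_s = -122.0
# Synaptic reversal potentials used to isolate components
reversal_exc_mV = 20.0
reversal_inh_mV = -45.0
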