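# Default study conditions for the synthetic generator.  Omitted fields
# (compound_stats, band_library) fall back to the bundled fixtures:
# the published per-compound averages/SDs and the fixed synthetic band
# library.  All fields of GeneratorConfig may be set here.
n_samples: 36
within_attribute_correlation: 0.6
background_scale: 1.0
scatter_offset_sd: 0.01
scatter_gain_log_sd: 0.005
noise_sd: 0.002
n_panelists: 30
panelist_sd: 0.3
panel_noise_sd: 0.5
panel_effect_scale: 1.0
panel_cutpoints: [-0.5, 0.5, 1.5]
panel_modality: odour
seed: 0
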