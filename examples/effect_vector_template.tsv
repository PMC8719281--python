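# Template meta-analytic effect-size vector.
# Replace the placeholder zeros with published case-control
# standardized effect sizes (structural deficits negative).
phenotype	effect
thk_bankssts	0.0
thk_caudalanteriorcingulate	0.0
thk_caudalmiddlefrontal	0.0
thk_cuneus	0.0
thk_entorhinal	0.0
thk_fusiform	0.0
thk_inferiorparietal	0.0
thk_inferiortemporal	0.0
thk_insula	0.0
thk_isthmuscingulate	0.0
thk_lateraloccipital	0.0
thk_lateralorbitofrontal	0.0
thk_lingual	0.0
thk_medialorbitofrontal	0.0
thk_middletemporal	0.0
thk_paracentral	0.0
thk_parahippocampal	0.0
thk_parsopercularis	0.0
thk_parsorbitalis	0.0
thk_parstriangularis	0.0
thk_pericalcarine	0.0
thk_postcentral	0.0
thk_posteriorcingulate	0.0
thk_precentral	0.0
thk_precuneus	0.0
thk_rostralanteriorcingulate	0.0
thk_rostralmiddlefrontal	0.0
thk_superiorfrontal	0.0
thk_superiorparietal	0.0
thk_superiortemporal	0.0
thk_supramarginal	0.0
thk_temporalpole	0.0
thk_transversetemporal	0.0
fa_acr	0.0
fa_alic	0.0
fa_bcc	0.0
fa_cgc	0.0
fa_cgh	0.0
fa_cr	0.0
fa_cst	0.0
fa_ec	0.0
fa_fx	0.0
fa_fxst	0.0
fa_gcc	0.0
fa_ic	0.0
fa_ifo	0.0
fa_pcr	0.0
fa_plic	0.0
fa_ptr	0.0
fa_rlic	0.0
fa_scc	0.0
fa_scr	0.0
fa_sfo	0.0
fa_slf	0.0
fa_ss	0.0
fa_unc	0.0
fa_averagefa	0.0
vol_thalamus	0.0
vol_caudate	0.0
vol_putamen	0.0
vol_pallidum	0.0
vol_hippocampus	0.0
vol_amygdala	0.0
vol_accumbens	0.0
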