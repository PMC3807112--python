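reaction_id	equation	gpr	subsystem
ACC	accoa_c[c] + atp_c[b] + co2_c[b] => malcoa_c[c] + adp_c[b] + pi_c[b]	ACACA	fatty acid synthesis
FAS	acyl_c[c] + malcoa_c[c] + 2 nadph_c[b] => acylx_c[c] + co2_c[b] + 2 nadp_c[b] + coa_c[b]	FASN	fatty acid synthesis
CPT1	acylx_c[c] + crn_c[b] => acylxcrn_c[c] + coa_c[b]	CPT1C	carnitine shuttle
CACT	acylxcrn_c[c] => acylxcrn_m[m]	SLC25A20	carnitine shuttle
CPT2	acylxcrn_m[m] + coa_m[b] => acylx_m[m] + crn_m[b]	CPT2	carnitine shuttle
BOX	acylx_m[m] + fad_m[b] + nad_m[b] + coa_m[b] => acyl_m[m] + accoa_m[m] + fadh2_m[b] + nadh_m[b]	ACADM and HADHA	beta oxidation
RET	acyl_m[m] => acyl_c[c]		carrier return (synthetic amortization step)
CS	accoa_m[m] + oaa_m[m] => cit_m[m] + coa_m[b]	CS	citrate shuttle
CMA	cit_m[m] + mal_c[c] => cit_c[c] + mal_m[m]	SLC25A1	citrate shuttle
ACL	cit_c[c] + atp_c[b] + coa_c[b] => accoa_c[c] + oaa_c[c] + adp_c[b] + pi_c[b]	ACLY	citrate shuttle
MDHC	oaa_c[c] + nadh_c[b] => mal_c[c] + nad_c[b]	MDH1	citrate shuttle
MDHM	mal_m[m] + nad_m[b] => oaa_m[m] + nadh_m[b]	MDH2	citrate shuttle
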