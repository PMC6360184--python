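# Synthetic TENM4 domain architecture (2769 aa). Residue boundaries are
# illustrative stand-ins chosen to reproduce published qualitative domain
# assignments; replace with curated coordinates for real analyses.
protein_id	protein_length	region_name	class	aa_start	aa_end
TENM4	2769	teneurin_N_terminal	N_terminal	1	420
TENM4	2769	transmembrane	transmembrane	421	445
TENM4	2769	EGF_like_repeats	EGF_like	600	950
TENM4	2769	NHL_repeats	NHL	1150	1550
TENM4	2769	YD_repeats	YD_repeat	1850	2450
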