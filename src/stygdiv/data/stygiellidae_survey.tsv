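species	culture	clone	pyrotag_v4	pyrotag_v9	pyrotag_v6v8
Stygiella incarcerata	NP	NP	0	NP	0
Stygiella adhaerens	NP	NP	0	0	0
Stygiella agilis	NP	NP	0	0	0
Stygiella cryptica	NP	0	0	0	0
Velundella trypanoides	NP	NP	0	NP	0
Velundella nauta	NP	0	0	0	0
EC I	0	NP	1	NP	0
EC II	0	NP	0	NP	0
EC III	0	NP	0	0	0
EC IV	0	NP	0	NP	56
EC V	0	0	0	26	0
unresolved	0	0	0	NP	0
TOTAL	21	83	1	572	56
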