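word	include	exclusion_reason	notes	inflections
Angst	true	none		Angst,Ängste
Furcht	true	none		Furcht
Sorge	true	none		Sorge,Sorgen
Panik	true	none		Panik
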