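word	include	exclusion_reason	notes	inflections
depression	true	none		depression,depressions
sadness	true	none		sadness
melancholy	true	none		melancholy
hopelessness	true	none		hopelessness
fatigue	true	none		fatigue,fatigues
gloom	false	double_meaning	weather sense flagged by native speakers	
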