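word	include	exclusion_reason	notes	inflections
computer	true	none		computer,computers
internet	true	none		internet
software	true	none		software
digital	true	none		digital
online	true	none		online
automation	true	none		automation
platform	false	broader_semantic	broader semantic meaning	
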