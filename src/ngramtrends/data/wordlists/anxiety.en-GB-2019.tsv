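word	include	exclusion_reason	notes	inflections
fear	true	none		fear,fears,feared,fearing
anxiety	true	none		anxiety,anxieties
worry	true	none		worry,worries,worried
panic	true	none		panic,panics
phobia	true	none		phobia,phobias
dread	true	none		dread,dreads,dreaded
interest	false	broader_semantic	broader semantic meaning	
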