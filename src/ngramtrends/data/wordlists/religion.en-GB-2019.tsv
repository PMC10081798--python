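word	include	exclusion_reason	notes	inflections
God	true	none		God,Gods
angel	true	none		angel,angels
clergy	true	none		clergy
prayer	true	none		prayer,prayers
faith	true	none		faith,faiths
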