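# version: 1.0-default
# Editable default additional-direction weights (section C): extra
# administration instructions that add complexity beyond form and frequency.
item_key	weight	notes
break_tablet	1	break or halve tablet
multiple_units	1	multiple units at one time
specific_time	1	take at a specific time of day
with_food	1	take with or after food
empty_stomach	1	take on an empty stomach
dissolve	1	dissolve or mix before administration
taper	2	tapering or escalating dose
alternating_dose	2	alternating dose regimen
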