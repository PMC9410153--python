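# version: 1.0-default
# Editable default dosage-form weights (section A). One row per dosage-form
# item key; weights follow the familiar ordering of the 65-item outpatient
# instrument (oral solids lightest, inhaled/ophthalmic routes heavier).
item_key	weight	notes
tablet	1	oral tablet
capsule	1	oral capsule
liquid	2	oral solution or suspension
sublingual	2	sublingual tablet or spray
gargle	2	gargle or mouthwash
inhaler	4	metered-dose inhaler
accuhaler	3	dry-powder inhaler
nebulizer	5	nebulised solution
oxygen	3	oxygen via mask or cannula
injection	3	subcutaneous or intramuscular injection
iv_infusion	4	intravenous infusion
patch	2	transdermal patch
topical	2	cream, ointment or paste
eye_drops	3	ophthalmic drops
ear_drops	3	otic drops
nasal_spray	2	intranasal spray
suppository	2	rectal suppository
enema	2	rectal enema
dressing	3	medicated dressing
powder	3	powder or granules
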