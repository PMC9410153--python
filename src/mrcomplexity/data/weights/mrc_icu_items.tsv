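# version: 1.0-default
# Editable default item weights for the critical-care medication regimen
# complexity score. Each listed agent or agent class contributes a fixed
# point weight once per regimen. The vancomycin (3) and continuous IV
# saline (1) entries reproduce the two published anchor weights; the
# remaining rows are editable defaults spanning the instrument's item
# categories (monitored anti-infectives, titratable infusions, high-alert
# agents) and should be replaced with a site's licensed weight table for
# clinical use.
item_key	weight	notes
vancomycin	3	serum-level monitored glycopeptide (published anchor)
continuous_iv_saline	1	continuous intravenous saline (published anchor)
aminoglycoside	3	serum-level monitored aminoglycoside
amphotericin	4	systemic antifungal, infusion-reaction risk
digoxin	3	narrow therapeutic index cardiac glycoside
phenytoin	3	serum-level monitored antiepileptic
warfarin	2	INR-monitored oral anticoagulant
argatroban	3	direct thrombin inhibitor infusion
heparin_infusion	2	titrated anticoagulant infusion
insulin_infusion	2	titrated insulin infusion
sliding_scale_insulin	1	correction-scale insulin
vasopressin	1	fixed-rate vasopressor infusion
norepinephrine_infusion	1	titratable vasopressor infusion
epinephrine_infusion	1	titratable vasopressor infusion
phenylephrine_infusion	1	titratable vasopressor infusion
dopamine_infusion	1	titratable vasopressor infusion
dobutamine_infusion	1	titratable inotrope infusion
amiodarone_infusion	3	antiarrhythmic infusion
propofol_infusion	1	continuous sedative infusion
dexmedetomidine_infusion	1	continuous sedative infusion
fentanyl_infusion	2	continuous opioid infusion
midazolam_infusion	2	continuous benzodiazepine infusion
ketamine_infusion	2	continuous dissociative analgesic infusion
cisatracurium_infusion	2	continuous neuromuscular blocker infusion
iv_fluid_with_additives	2	continuous IV fluid with additives
tpn	2	total parenteral nutrition
blood_product	2	blood-product transfusion
chemotherapy	3	cytotoxic chemotherapy
clozapine	2	monitored antipsychotic
inhaled_epoprostenol	3	inhaled pulmonary vasodilator
electrolyte_protocol	1	protocolised electrolyte replacement
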