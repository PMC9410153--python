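# version: 1.0-default
# Editable default dosing-frequency weights (section B). PRN ("as needed")
# schedules carry reduced weights but are scored: scheduled and as-needed
# medications both count toward regimen complexity.
item_key	weight	notes
once_daily	1	once daily
twice_daily	2	twice daily
three_times_daily	3	three times daily
four_times_daily	4	four times daily
q12h	2.5	every 12 hours
q8h	3.5	every 8 hours
q6h	4.5	every 6 hours
q4h	6.5	every 4 hours
q2h	12.5	every 2 hours
continuous	2	continuous infusion schedule
once_daily_prn	0.5	once daily as needed
twice_daily_prn	1	twice daily as needed
three_times_daily_prn	1.5	three times daily as needed
four_times_daily_prn	2	four times daily as needed
q6h_prn	2.5	every 6 hours as needed
q4h_prn	3.5	every 4 hours as needed
once_weekly	0.5	once weekly
on_alternate_days	2	alternate-day dosing
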