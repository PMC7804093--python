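# Hand-digitized per-survey prevalence / mean-intensity / sample-size table for
# larval Trifur sp. copepods on five larval fish species, Isla Santa Maria (ISM)
# and Punta Coloso (COL), northern Chile; surveys 1-5 austral spring-summer,
# 6-10 autumn-winter. prevalence_pct and mean_intensity are the printed values
# (empty prevalence = cell printed as bracketed n only, i.e. no parasitized
# larvae); n_collected is the printed bracketed count. Rows printed with fewer
# entries than the five species columns are assigned positionally to the
# alphabetically-first species and flagged ambiguous=1 (species identity is not
# recoverable from the printed layout); integer counts are reconstructed
# downstream, never stored here.
area,season,survey_id,species,prevalence_pct,mean_intensity,n_collected,ambiguous,note
ISM,spring_summer,1,Ac,,,3,1,short_row
ISM,spring_summer,1,Gm,,,0,1,short_row
ISM,spring_summer,1,Hc,,,0,1,short_row
ISM,spring_summer,1,Msp,,,1,1,short_row
ISM,spring_summer,2,Ac,,,8,1,short_row
ISM,spring_summer,2,Gm,16.67,1,6,1,short_row
ISM,spring_summer,2,Hc,,,28,1,short_row
ISM,spring_summer,2,Msp,,,2,1,short_row
ISM,spring_summer,3,Ac,31.79,1,56,1,short_row
ISM,spring_summer,3,Gm,12.5,1,8,1,short_row
ISM,spring_summer,3,Hc,4.76,1,63,1,short_row
ISM,spring_summer,3,Msp,,1,1,1,short_row;prevalence_not_printed
ISM,spring_summer,4,Ac,3.57,1,28,1,short_row
ISM,spring_summer,4,Gm,,,24,1,short_row
ISM,spring_summer,4,Hc,,,13,1,short_row
ISM,spring_summer,4,Msp,,,3,1,short_row
ISM,spring_summer,5,Ac,,,18,1,short_row
ISM,spring_summer,5,Gm,,,3,1,short_row
ISM,spring_summer,5,Hc,,,2,1,short_row
ISM,spring_summer,5,Msp,,,0,1,short_row
ISM,autumn_winter,6,Ac,0.55,1,1267,0,
ISM,autumn_winter,6,Gm,3.51,1,57,0,
ISM,autumn_winter,6,Hc,6.50,1.04,1492,0,
ISM,autumn_winter,6,Msp,2.24,1,134,0,
ISM,autumn_winter,6,Oj,2.42,1,124,0,
ISM,autumn_winter,7,Ac,0.57,1,353,0,
ISM,autumn_winter,7,Gm,,,11,0,
ISM,autumn_winter,7,Hc,0.94,1.33,320,0,
ISM,autumn_winter,7,Msp,,,15,0,
ISM,autumn_winter,7,Oj,12.5,1,8,0,
ISM,autumn_winter,8,Ac,1.40,1.05,1502,0,
ISM,autumn_winter,8,Gm,1.23,1,81,0,
ISM,autumn_winter,8,Hc,3.28,1.07,1372,0,
ISM,autumn_winter,8,Msp,1.98,1,101,0,
ISM,autumn_winter,8,Oj,6.40,1.22,172,0,
ISM,autumn_winter,9,Ac,,,642,1,duplicate_n_in_row
ISM,autumn_winter,9,Gm,1.22,1,82,0,
ISM,autumn_winter,9,Hc,2.18,1,642,1,duplicate_n_in_row
ISM,autumn_winter,9,Msp,,,5,0,
ISM,autumn_winter,9,Oj,,,17,0,
ISM,autumn_winter,10,Ac,0.63,1,3949,0,
ISM,autumn_winter,10,Gm,10.81,1,74,0,
ISM,autumn_winter,10,Hc,1.23,1.01,5843,0,
ISM,autumn_winter,10,Msp,,,0,0,
ISM,autumn_winter,10,Oj,4.76,1,21,0,
COL,spring_summer,1,Ac,,,3,1,short_row
COL,spring_summer,1,Gm,7.69,1,13,1,short_row
COL,spring_summer,1,Hc,,,2,1,short_row
COL,spring_summer,2,Ac,,,4,1,short_row
COL,spring_summer,2,Gm,26.09,1,23,1,short_row
COL,spring_summer,2,Hc,,,0,1,short_row
COL,spring_summer,3,Ac,,,3,1,short_row
COL,spring_summer,3,Gm,4.55,2,44,1,short_row
COL,spring_summer,3,Hc,,,0,1,short_row
COL,spring_summer,4,Ac,,,4,1,short_row
COL,spring_summer,4,Gm,13.64,1,22,1,short_row
COL,spring_summer,4,Hc,,,1,1,short_row
COL,spring_summer,5,Ac,,,0,1,short_row
COL,spring_summer,5,Gm,,,0,1,short_row
COL,spring_summer,5,Hc,,,0,1,short_row
COL,autumn_winter,6,Ac,,,1,1,short_row
COL,autumn_winter,6,Gm,,,9,1,short_row
COL,autumn_winter,6,Hc,,,1,1,short_row
COL,autumn_winter,6,Msp,,,0,1,short_row
COL,autumn_winter,7,Ac,,,5,1,short_row
COL,autumn_winter,7,Gm,,,9,1,short_row
COL,autumn_winter,7,Hc,,,1,1,short_row
COL,autumn_winter,7,Msp,,,1,1,short_row
COL,autumn_winter,8,Ac,,,80,1,short_row
COL,autumn_winter,8,Gm,,,81,1,short_row
COL,autumn_winter,8,Hc,,,1,1,short_row
COL,autumn_winter,8,Msp,,,30,1,short_row
COL,autumn_winter,9,Ac,,,114,1,short_row
COL,autumn_winter,9,Gm,11.6,1.4,138,1,short_row
COL,autumn_winter,9,Hc,,,12,1,short_row
COL,autumn_winter,9,Msp,14.29,1.6,28,1,short_row
COL,autumn_winter,10,Ac,1.50,1,200,1,short_row
COL,autumn_winter,10,Gm,3.6,1,111,1,short_row
COL,autumn_winter,10,Hc,2.50,1,40,1,short_row
COL,autumn_winter,10,Msp,10.0,1,10,1,short_row
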