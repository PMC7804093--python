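# Hand-digitized per-species body-length summary: ranges (paper units; fish
# lengths measured to the nearest 0.1 cm, parasite lengths in micrometres with
# unit-ambiguous printed ranges) of unparasitized and parasitized fish larvae,
# parasite size ranges, and Spearman correlations between parasitized-larva
# length and ectoparasite length per area (Isla Santa Maria ISM, Punta Coloso
# COL). Parenthesized sample sizes as printed; sig_* = printed significance
# star (P < 0.05); empty correlation = printed dash.
species,unpar_min,unpar_max,n_unpar,par_min,par_max,n_par,psize_min,psize_max,r_ism,n_ism,sig_ism,r_col,n_col,sig_col
Hc,2.9,9.1,109,3.8,10.1,235,0.28,1.72,0.626,234,0,1.000,1,0
Ac,3.5,9.8,151,3.0,8.1,61,0.26,2.88,0.740,58,1,1.000,3,0
Gm,3.1,7.4,132,1.88,6.6,46,0.18,2.35,0.652,14,1,0.871,32,1
Msp,2.2,5.5,37,4.1,6.1,6,0.55,2.08,0.982,6,1,,,0
Oj,2.2,4.2,35,2.3,7.5,21,0.54,0.97,0.700,16,0,0.684,5,0
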