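assay_id	group	o2_fraction_before	o2_fraction_after	gas_volume_l	temperature_k	pressure_atm	colony_count	cells_per_colony	qc_discard
25C_assay01	25C	0.2095	0.20479546703619256	0.5	298.15	1.0	133	137976334.4324428	False
25C_assay02	25C	0.2095	0.20572551665341837	0.5	298.15	1.0	136	128594671.46243063	False
25C_assay03	25C	0.2095	0.20411262352414022	0.5	298.15	1.0	156	145039474.3534286	False
25C_assay04	25C	0.2095	0.20483402465204392	0.5	298.15	1.0	158	123522809.52917844	False
28C_assay01	28C	0.2095	0.20458469532903667	0.5	301.15	1.0	151	143525404.82099584	False
28C_assay02	28C	0.2095	0.20569672464597175	0.5	301.15	1.0	130	112746555.45061898	False
28C_assay03	28C	0.2095	0.20442561746843585	0.5	301.15	1.0	157	129589958.59534915	False
28C_assay04	28C	0.2095	0.20316325011170644	0.5	301.15	1.0	160	136922048.9279155	False
37C_assay01	37C	0.2095	0.20187325108228749	0.5	310.15	1.0	151	142129950.33911765	False
37C_assay02	37C	0.2095	0.2016991420660046	0.5	310.15	1.0	168	119009941.81509665	False
37C_assay03	37C	0.2095	0.20147177245623782	0.5	310.15	1.0	158	144434360.22917858	False
37C_assay04	37C	0.2095	0.20160813800787597	0.5	310.15	1.0	146	138931609.0500492	False
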