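sensor_id	name	oxide	specificity	lower_detection_limit_ppm
1	TGS 813	SnO2	Methane, Ethane, Propane	500
2	TGS 822	SnO2	Organic solvent vapors	50
3	TGS 825	SnO2	Low conc. of H2S	5
4	TGS 826	SnO2	Ammonia	30
5	TGS 2620	SnO2	Alcohol and organic solvent vapors	50
6	SB-11A	SnO2	Hydrocarbon	100
7	SB-AQ8	WO3	VOCs	1.0
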