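cross_id	1	2	3	4	5	6	7	8
WR04	0	0	0	0	0	0	0	0
WR05	0	0	0	0	0	0	0	0
WR06	0	0	0	0	0	0	0	0
WR07	0	0	0	0	0	0	0	0
BR01	0	0	0	-0.07	0.06	0	0	0
BR02	0	0	0	0.07	-0.05	0	0	0
BR12	-0.05	0	0.1	0	0	0.04	-0.02	0
BR10	-0.02	0	0.02	0	-0.02	0	0	0
BR11	0	0	0	0	0	0	0	0
BS09	0	0	0.1	0.06	-0.19	-0.02	0.19	-0.08
BS08	0	0	-0.02	0	0	0.02	0	0
BS15	0	0	0.02	-0.08	0.13	0	0	0
BS16	0.02	0.02	0.03	-0.05	0.06	0	0	0
BS14	-0.02	0	0	-0.02	0	0	0	0
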