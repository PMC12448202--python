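# Cross metadata for the 14 published F1 hybrids.
# Only Pais09 (mother of BR01, father of BR02) and Hall2.2 (shared by BS08 and
# BS09; assigned as father of both here, the published role is unstated) are
# real parent IDs. Every other parent ID is a synthetic placeholder
# (<cross>.m / <cross>.f) that carries no information beyond being distinct.
cross_id	group	mother	father
WR04	WR	WR04.m	WR04.f
WR05	WR	WR05.m	WR05.f
WR06	WR	WR06.m	WR06.f
WR07	WR	WR07.m	WR07.f
BR01	BR	Pais09	BR01.f
BR02	BR	BR02.m	Pais09
BR12	BR	BR12.m	BR12.f
BR10	BR	BR10.m	BR10.f
BR11	BR	BR11.m	BR11.f
BS09	BS	BS09.m	Hall2.2
BS08	BS	BS08.m	Hall2.2
BS15	BS	BS15.m	BS15.f
BS16	BS	BS16.m	BS16.f
BS14	BS	BS14.m	BS14.f
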