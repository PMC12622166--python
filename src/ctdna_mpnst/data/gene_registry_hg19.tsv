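gene	chrom	start	end	role
CDKN2A	9	21967751	21995300	feature
CDKN2B	9	22002902	22009280	feature
TP53	17	7571720	7590868	feature
SUZ12	17	30264063	30357651	feature
EED	11	85955590	85989795	feature
MYC	8	128748315	128753680	chr8q
RAD21	8	117858174	117887106	chr8q
TCEA1	8	54967148	55011910	chr8q
PLAG1	8	57073467	57123859	chr8q
CHCHD7	8	57125985	57132922	chr8q
NCOA2	8	71028818	71316222	chr8q
NF1	17	29421945	29704695	other
MTAP	9	21802635	21941115	other
TERT	5	1253287	1295162	other
COA3	17	40854513	40856300	other
ATRX	X	76760356	77041702	excluded
DNMT3A	2	25455845	25565459	chip
TET2	4	106067032	106200973	chip
ASXL1	20	30946134	31027122	chip
JAK2	9	4985033	5128183	chip
SF3B1	2	198254508	198299817	chip
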