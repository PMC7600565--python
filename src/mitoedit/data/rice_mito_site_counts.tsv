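gene	n_sites
atp1	5
atp6	18
atp9	8
ccmB	35
ccmC	35
ccmFC	27
ccmFN	38
cob	19
cox1	5
cox2	21
cox3	13
matR	16
nad1	26
nad2	32
nad3	19
nad4	21
nad4L	11
nad5	13
nad6	18
nad7	34
nad9	13
orf25	9
orf288	3
orfB	7
orfX	37
rpl2	1
rpl5	1
rpl16	13
rps1	3
rps2	10
rps3	14
rps4	18
rps7	2
pseudo-rps11	5
rps12	6
rps13	7
rps19	6
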