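family	genera	species	individuals
Akravidae	1	1	7
Bothriuridae	14	16	44
Buthidae	56	60	138
Chactidae	12	16	49
Chaerilidae	1	4	18
Diplocentridae	9	12	24
Euscorpiidae	4	7	10
Hemiscorpiidae	1	1	2
Heteroscorpionidae	1	3	8
Hormuridae	10	14	38
Iuridae	9	11	28
Pseudochactidae	3	3	22
Scorpionidae	4	5	37
Scorpiopidae	4	5	11
Superstitioniidae	1	1	4
Troglotayosicidae	2	2	5
Typhlochactidae	4	6	7
Urodacidae	2	3	5
Vaejovidae	22	26	62
Total	160	196	519
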