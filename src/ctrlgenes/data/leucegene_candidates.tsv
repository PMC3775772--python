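gene	stratum	mean	cv	mfc
HNRNPK	high	220,4	16,5	2,0
PCBP2	high	188,3	19,4	3,1
SLC25A3	high	149,1	19,8	2,5
GNB1	high	130,1	19,8	3,3
CCNI	high	176,2	20,9	2,9
HNRNPU	high	100,2	21,3	3,4
HNRNPL	high	145,7	21,3	2,9
HNRNPD	high	124,4	22,4	3,1
CSDE1	high	137,1	22,5	3,6
SRSF5	high	282,4	23,2	2,9
ATP5B	high	307,6	23,2	2,5
SSR2	high	136,7	23,7	3,4
MYL12B	high	137,9	23,8	3,5
HNRNPA2B1	high	238,2	23,9	3,6
HNRNPC	high	125,2	24,3	3,3
ARF1	high	166,7	24,6	2,6
RHOA	high	307,0	24,6	2,9
PSME1	high	147,7	24,7	3,7
DDX5	high	302,4	24,8	3,3
SRP14	high	132,2	24,9	3,2
MORF4L1	mid	85,5	16,4	3,0
PSMD7	mid	52,4	18,2	2,3
PSMD6	mid	45,8	18,4	2,2
PSMA1	mid	53,7	18,8	2,6
SEC31A	mid	36,0	18,8	2,5
SRPR	mid	50,7	18,9	2,6
VCP	mid	78,8	19,0	2,6
PSMF1	mid	27,1	19,2	3,4
MRFAP1	mid	90,3	19,4	2,2
KHDRBS1	mid	80,9	19,4	2,5
USP4	mid	27,0	19,4	2,8
DLST	mid	34,9	19,6	2,6
VPS4A	mid	35,1	19,8	2,7
SUPT6H	mid	28,8	19,9	3,4
SF3B2	mid	82,9	19,9	2,3
C1orf144	mid	44,7	19,9	3,8
NOL7	mid	38,6	19,9	2,3
EIF4H	mid	95,8	20,0	3,3
ZNF207	mid	95,5	22,1	2,9
UBE2I	mid	56,1	24,2	4,1
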