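gene	leucegene_mean	leucegene_cv	leucegene_mfc	tcga_mean	tcga_cv	tcga_mfc
TBP	8,1	22,8	2,5	6,7	44,9	12,2
YWHAZ	144,6	27,2	3,2	284,9	70,0	55,1
PGK1	189,9	28,4	3,4	212,6	62,0	31,0
LDHA	144,7	34,2	10,2	401,7	66,6	42,4
ALDOA	244,0	35,5	3,6	736,7	60,3	105,0
HPRT1	30,7	40,0	6,7	23,1	56,5	304,5
ABL1	17,0	40,1	5,7	13,9	39,8	26,9
SDHA	31,1	40,7	12,2	52,9	61,8	74,2
UBC	499,1	41,3	5,2	1260,8	47,0	102,0
GAPDH	2206,7	42,6	8,3	1954,8	70,7	60,7
ACTB	1617,9	48,7	5,4	2069,5	47,4	45,2
G6PD	43,5	52,6	6,9	23,9	106,7	639,5
VIM	1700,4	53,4	17,0	824,2	90,0	192,0
TUBA1A	251,0	53,8	8,4	148,7	55,6	64,6
PFKP	56,4	55,3	13,3	52,9	116,2	521,0
B2M	1798,6	55,5	13,9	2506,3	61,4	91,9
GUSB	45,6	55,9	10,6	44,7	61,2	84,0
PGAM1	12,9	65,5	14,4	125,4	60,1	95,4
HMBS	18,2	69,1	31,7	11,4	80,5	202,8
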