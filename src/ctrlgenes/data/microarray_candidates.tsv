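gene	leucegene_mean	leucegene_cv	leucegene_mfc	tcga_mean	tcga_cv	tcga_mfc
SRP14	132,2	24,9	3,2	145,6	31,8	10,9
RPL4	1276,1	40,4	5,6	734,0	44,3	51,0
RPL6	324,0	43,1	6,5	565,4	48,9	78,6
OAZ1	421,9	44,4	4,5	273,7	42,5	18,5
RPL22	156,6	45,4	9,0	192,4	39,2	25,8
RPL24	798,9	48,1	7,5	778,6	54,3	36,5
RPL27	1292,6	48,8	10,5	682,5	60,4	38,1
RPS13	935,8	55,0	8,8	662,8	47,7	29,3
RPS20	636,3	55,1	8,0	667,0	58,6	52,9
RPS29	559,0	56,2	8,7	490,9	65,8	100,3
RPS16	1104,4	61,6	9,2	794,2	82,0	192,1
RPL9	99,7	124,3	72,6	1007,0	66,3	1208,3
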