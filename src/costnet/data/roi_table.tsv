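name	x	y	z	category	subcortical
SMA1	-4	-2	68	SI>ET,SI>CON	0
PreSMA1	6	16	46	SI>ET,SI>CON	0
VLPFC1	-50	4	4	SI>ET,SI>CON	0
VLPFC2	44	14	2	SI>ET,SI>CON	0
VLPFC3	56	14	0	SI>ET,SI>CON	0
DLPFC1	34	40	36	SI>ET,SI>CON	0
APFC	40	46	2	SI>ET,SI>CON	0
INS1	-32	18	4	SI>ET,SI>CON	0
INS2	30	20	6	SI>ET,SI>CON	0
Thal1	-14	-18	6	SI>ET,SI>CON	1
Thal2	14	-16	8	SI>ET,SI>CON	1
LOA1	50	-54	-6	SI>ET,SI>CON	0
PMd1	-20	-2	62	SI>ET,SI>CON,ET>CON	0
PMd2	24	-4	58	SI>ET,SI>CON,ET>CON	0
IPL1	36	-44	50	SI>ET,SI>CON,ET>CON	0
Put1	-24	2	4	SI>ET,SI>CON,ET>CON	1
Put2	24	4	8	SI>ET,SI>CON,ET>CON	1
PreSMA2	-6	6	48	SI>CON,ET>CON	0
PreSMA3	6	4	52	SI>CON,ET>CON	0
PMd3	-32	-12	56	SI>CON,ET>CON	0
PMd4	38	-10	62	SI>CON,ET>CON	0
IPL2	-48	-42	54	SI>CON,ET>CON	0
IPL3	-32	-50	52	SI>CON,ET>CON	0
IPL4	46	-34	40	SI>CON,ET>CON	0
DLPFC2	-56	4	36	SI>CON,ET>CON	0
DLPFC3	52	6	36	SI>CON,ET>CON	0
IPL5	-28	-60	58	SI>CON,ET>CON	0
IPL6	18	-66	58	SI>CON,ET>CON	0
IPL7	-16	-72	56	SI>CON,ET>CON	0
SOG1	30	-68	32	SI>CON,ET>CON	0
SOG2	-26	-74	24	SI>CON,ET>CON	0
SOG3	32	-74	26	SI>CON,ET>CON	0
SOG4	-28	-82	22	SI>CON,ET>CON	0
MOG1	-32	-86	12	SI>CON,ET>CON	0
MOG2	32	-80	6	SI>CON,ET>CON	0
MOG3	40	-74	4	SI>CON,ET>CON	0
LG1	-16	-86	4	SI>CON,ET>CON	0
LG2	18	-90	2	SI>CON,ET>CON	0
LG3	-10	-84	-10	SI>CON,ET>CON	0
LG4	14	-84	-12	SI>CON,ET>CON	0
FG1	-24	-76	-14	SI>CON,ET>CON	0
FG2	22	-76	-14	SI>CON,ET>CON	0
LOA2	-48	-68	-8	SI>CON,ET>CON	0
Cereb1	6	-70	-20	SI>CON,ET>CON	0
M1-1	-40	-20	52	MTR_left_vs_right	0
Cereb2	-26	-62	-24	MTR_left_vs_right	0
Cereb3	28	-58	-24	MTR_left_vs_right	0
Cereb4	-28	-66	-52	MTR_left_vs_right	0
Cereb5	28	-66	-52	MTR_left_vs_right	0
M1-2	40	-22	54	MTR_left_vs_right	0
SMA2	-6	-20	50	MTR_left_vs_right	0
SMA3	8	-24	50	MTR_left_vs_right	0
InsPost1	-36	-32	22	MTR_left_vs_right	0
InsPost2	42	-22	20	MTR_left_vs_right	0
Cereb6	-18	-58	-20	MTR_left_vs_right	0
Cereb7	20	-52	-20	MTR_left_vs_right	0
Thal3	16	-20	2	MTR_left_vs_right	1
PutPost	32	-12	2	MTR_left_vs_right	1
Caudate1	-14	12	12	ETC	1
Caudate2	14	12	12	ETC	1
VS1	-10	14	-6	ETC	1
VS2	10	14	-6	ETC	1
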