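sample_id	response	crs	hlh
P01	OR	low	yes
P02	OR	low	no
P03	OR	high	no
P04	OR	low	yes
P05	OR	low	no
P06	OR	low	yes
P07	OR	low	no
P08	OR	low	yes
P09	OR	high	no
P10	OR	low	no
P11	OR	low	yes
P12	OR	low	no
P13	OR	low	yes
P14	OR	low	no
P15	OR	low	yes
P16	OR	low	no
P17	OR	high	no
P18	OR	low	yes
P19	OR	low	no
P20	OR	low	yes
P21	OR	low	no
P22	OR	low	yes
P23	OR	low	no
P24	NR	low	yes
P25	NR	high	no
P26	NR	low	yes
P27	NR	low	yes
P28	NR	low	no
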