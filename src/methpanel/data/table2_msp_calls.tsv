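gene	BL41	HLY-1	K422	Namwalwa	NUDHL1	Ocily-10	Ocily-19	Ocily-2	Ocily-3	Ocily-7	Raji	Ramos	Ros-50	SC-1	Sudhl10	Sudhl4	Sudhl6	U2932
PPP1R14A	M	U/M	M	M	M	U/M	M	M	M	M	M	M	M	M	M	M	M	U/M
DSP	U/M	M	M	M	U/M	U/M	U/M	U/M	M	U/M	M	U/M	U/M	U/M	U/M	M	U/M	U
FZD8	M	M	M	U/M	M	M	M	M	U	M	M	M	U/M	M	M	M	M	U
NR4A2	U/M	U/M	U/M	U/M	U/M	U	U/M	U/M	U	U/M	M	M	U/M	U/M	U/M	U/M	U/M	U/M
MTSS1	U/M	U/M	U/M	U/M	U/M	U	U/M	U/M	U	U/M	U/M	U/M	U/M	U	U/M	U/M	U/M	U/M
KCNH2	M	U/M	U/M	U/M	U	U/M	M	U/M	U/M	U	U/M	M	U/M	U/M	U	U/M	U/M	U
KLF9	U/M	U	U/M	U/M	U/M	U/M	U	U/M	U/M	U/M	U/M	U/M	U	U	U/M	U/M	U/M	U
PTPN12	U/M	M	U	U	U	U/M	U	U/M	U/M	U/M	M	U/M	U	U/M	U/M	U	U	U
JAM3	U	U/M	U	U/M	U	U/M	U	U/M	M	U/M	M	U/M	U/M	U	U	U/M	U	U
TRIM36	U/M	U/M	M	U/M	U/M	U	U/M	U	U	U/M	M	U/M	U	U	U	U	U	U
MYLIP	U	U	M	U/M	U/M	U	U	U/M	U/M	U	U	M	U/M	U	M	U/M	U	U
AREG	U	U	U	U/M	U	U	U	U/M	U	U/M	U/M	U/M	U	U	U	U	U	U
KLF2	U	U	U	U	U	U	U	U	U/M	M	M	M	U	U	U	U/M	U	U
EPHA4	U	U/M	U	U	U/M	U	U	U	U	U	U/M	U/M	U	U	U	U	U/M	U
GNG7	U	U	U	U	U	M	U	U	M	U	U	U	U	U	U	U	U	U/M
RGS2	U	U	U	U	U	U	U/M	U	U	U	U/M	U	U	U	U	U	U	U
TMED	U	U	U	U	U	U	U	U	U/M	U	U	U/M	U	U	U	U	U	U
C10orf118	U	U	U	U	U	U	U	U	U	U	U/M	U	U	U	U	U	U	U
COMMD6	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
DUSP1	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
FOS	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
HERC1	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
JUN	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
JUNB	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
JUND	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
PITHD1	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
TXNIP	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
WBSCR16	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U	U
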