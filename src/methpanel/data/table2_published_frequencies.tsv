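gene	methylation_pct
PPP1R14A	100
DSP	94
FZD8	89
NR4A2	89
MTSS1	83
KCNH2	78
KLF9	72
PTPN12	56
JAM3	56
TRIM36	50
MYLIP	50
AREG	28
KLF2	28
EPHA4	28
GNG7	17
RGS2	11
TMED	11
C10orf118	6
COMMD6	0
DUSP1	0
FOS	0
HERC1	0
JUN	0
JUNB	0
JUND	0
PITHD1	0
TXNIP	0
WBSCR16	0
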