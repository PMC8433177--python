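AKR1B1
AL035706.1
ARL4C
ARRDC2
BTG2
COL4A1
COL4A2
CYTOR
EHD4
ERVW-1
FTOP1
GSN
HTR2A
IER5
IL27RA
INMT
LINC01725
LPAL2
NFKB2
PKM
S100A4
SOX5
TPM4
TRBC2
VIM
XYLB
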