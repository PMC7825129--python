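# Fixture gene panel: the genes named in the cohort's candidate tables
# plus a selection of established MAC / ocular-development panel genes.
# The full 307-entry screening panel is supplied by the user.
CRIM1
CHD7
FAT1
PTCH1
PUF60
BRPF1
TGFB2
TBX5
FZD7
PPP1R12A
ACTG1
EFTUD2
F11
MTNR1A
ZFP42
PAX6
SOX2
OTX2
RAX
VSX2
SHH
GDF6
GDF3
STRA6
ALDH1A3
RARB
MAB21L2
YAP1
BMP4
BMP7
SMOC1
PORCN
FOXE3
PITX2
PITX3
SALL2
SALL4
TENM3
ABCB6
ATOH7
C12orf57
CDON
SIX6
VAX1
HCCS
BCOR
NAA10
SCRIB
NRBP2
SEMA3E
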