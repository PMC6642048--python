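# 40-gene candidate immune-regulator panel used for the tumor-microenvironment
# co-expression screen. Groups: costimulatory, T-cell inhibitory, regulatory
# markers, metabolic checkpoints, myeloid-related checkpoints.
CD2
CD27
CD28
TNFRSF8
CD40
CD40LG
CD70
ICOS
ICOSLG
TNFRSF4
TNFSF4
TNFRSF9
CTLA4
PDCD1
CD274
PDCD1LG2
VSIR
CD160
TNFRSF14
CD200
CD200R1
TIGIT
CD276
VTCN1
BTLA
LAG3
HAVCR2
FOXP3
TNFRSF18
ADORA1
ADORA2A
ADORA2B
HK2
GLS
IDO1
TPI1
CD14
CSF1R
KIR2DL1
PVR
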