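# Per-residue interface propensity ("stickiness") scale from Levy, De &
# Teichmann (2012) PNAS 109:20461-20466, supporting information. version 1
residue,stickiness
ALA,0.0062
ARG,-0.7307
ASN,-0.2693
ASP,-0.7485
CYS,1.0372
GLN,-0.3409
GLU,-0.7893
GLY,-0.1771
HIS,0.1204
ILE,1.1109
LEU,0.9138
LYS,-1.1806
MET,1.0124
PHE,1.2727
PRO,-0.4114
SER,-0.1376
THR,-0.1510
TRP,0.7925
TYR,0.8806
VAL,0.7599
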