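# Interaction propensity ("stickiness") of amino acids at protein surfaces
# (Levy, De & Teichmann 2012). Dimensionless.
residue,value
A,0.0062
R,-0.0876
N,-0.2693
D,-0.7485
C,1.0372
Q,-0.4114
E,-0.7893
G,-0.1771
H,0.1204
I,1.1109
L,0.9138
K,-1.1806
M,1.0124
F,1.2727
P,-0.4114
S,0.1376
T,0.1031
W,0.7925
Y,0.8806
V,0.7599
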