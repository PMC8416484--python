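# Per-residue intrinsic aggregation-propensity values (a3v scale, v1).
# Transcribed from the published AGGRESCAN scale; dimensionless.
# One residue per line: <one-letter code><whitespace><value>
A -0.036
C 0.604
D -1.836
E -1.412
F 1.754
G -0.535
H -1.033
I 1.822
K -0.931
L 1.380
M 0.910
N -1.302
P -0.334
Q -1.231
R -1.240
S -0.294
T -0.159
V 1.594
W 1.037
Y 1.159
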