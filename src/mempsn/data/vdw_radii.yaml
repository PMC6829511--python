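# Van der Waals radii (Å) by element, used for Shrake-Rupley SASA when the
# topology carries no explicit per-atom radii.  Bondi (1964) values, the common
# default of SASA tools; edit to match another parameter set.
H: 1.20
C: 1.70
N: 1.55
O: 1.52
S: 1.80
P: 1.80
F: 1.47
CL: 1.75
K: 2.75
NA: 2.27
MG: 1.73
CA: 2.31
default: 1.70
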