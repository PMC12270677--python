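# Random-coil 1H alpha-proton chemical shifts (ppm, referenced to DSS),
# Wishart, Bigam, Holm, Hodges & Sykes (1995) J Biomol NMR 5:67-81.
# Cys value is for the reduced thiol form; cystine runs ~0.16 ppm downfield,
# which only offsets the secondary shift baseline uniformly for S-S peptides.
aa	ha
A	4.32
R	4.34
N	4.74
D	4.64
C	4.55
Q	4.34
E	4.35
G	3.96
H	4.73
I	4.17
L	4.34
K	4.32
M	4.48
F	4.62
P	4.42
S	4.47
T	4.35
W	4.66
Y	4.55
V	4.12
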