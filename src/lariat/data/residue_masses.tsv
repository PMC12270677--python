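# Standard amino-acid residue masses (Da), i.e. the mass each residue adds to
# a peptide chain (free amino acid minus one water).
# monoisotopic: IUPAC 2013 atomic masses, most abundant isotopes.
# average: IUPAC standard atomic weights (the ExPASy/CRC table).
# Peptide mass = sum(residues) + H2O (18.0105646863 mono / 18.01528 average).
aa	monoisotopic	average
G	57.02146	57.0513
A	71.03711	71.0779
S	87.03203	87.0773
P	97.05276	97.1152
V	99.06841	99.1311
T	101.04768	101.1039
C	103.00919	103.1429
L	113.08406	113.1576
I	113.08406	113.1576
N	114.04293	114.1026
D	115.02694	115.0874
Q	128.05858	128.1292
K	128.09496	128.1723
E	129.04259	129.1140
M	131.04049	131.1961
H	137.05891	137.1393
F	147.06841	147.1739
R	156.10111	156.1857
Y	163.06333	163.1733
W	186.07931	186.2099
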