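# Binary hydrophobicity classes used for editing-consequence statistics.
# S/T/H hydrophilic and L/F/M/I/Y/P hydrophobic are fixed by the observed
# plastid editing conversions (S>L, S>F, T>M, T>I, H>Y philic->phobic;
# P>S phobic->philic; P>L, L>F no exchange). The remaining residues follow
# the common binary assignment: A, V, C, G, W hydrophobic; charged and
# amide residues hydrophilic.
residue	class
A	hydrophobic
C	hydrophobic
D	hydrophilic
E	hydrophilic
F	hydrophobic
G	hydrophobic
H	hydrophilic
I	hydrophobic
K	hydrophilic
L	hydrophobic
M	hydrophobic
N	hydrophilic
P	hydrophobic
Q	hydrophilic
R	hydrophilic
S	hydrophilic
T	hydrophilic
V	hydrophobic
W	hydrophobic
Y	hydrophobic
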