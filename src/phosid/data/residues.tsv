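# Amino-acid residue elemental compositions (peptide-bond residues, no water).
# Residue masses are derived from these formulas and elements.tsv, keeping a
# single source of truth for all mass arithmetic.
# one_letter	formula
G	C2H3NO
A	C3H5NO
S	C3H5NO2
P	C5H7NO
V	C5H9NO
T	C4H7NO2
C	C3H5NOS
L	C6H11NO
I	C6H11NO
N	C4H6N2O2
D	C4H5NO3
Q	C5H8N2O2
K	C6H12N2O
E	C5H7NO3
M	C5H9NOS
H	C6H7N3O
F	C9H9NO
R	C6H12N4O
Y	C9H9NO2
W	C11H10N2O
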