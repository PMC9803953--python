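# Monoisotopic masses of the most abundant isotope, Da (CODATA/IUPAC).
# symbol	monoisotopic_mass
H	1.00782503207
C	12.0
N	14.0030740048
O	15.9949146196
P	30.97376163
S	31.97207100
Cl	34.96885268
F	18.99840322
Br	78.9183371
I	126.904473
Se	79.9165213
Na	22.9897692809
K	38.96370668
Ca	39.96259098
Fe	55.9349375
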