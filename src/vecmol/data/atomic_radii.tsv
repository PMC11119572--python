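# Element radii in Ångström used for sphere sizes.
# These are van der Waals radii as listed in the PubChem periodic table
# (values shown there in pm, converted here to Å).
# Unknown symbols fall back to 1.50 Å — see chem.DEFAULT_RADIUS.
# symbol	radius_angstrom
H	1.20
He	1.40
Li	1.82
Be	1.53
B	1.92
C	1.70
N	1.55
O	1.52
F	1.47
Ne	1.54
Na	2.27
Mg	1.73
Al	1.84
Si	2.10
P	1.80
S	1.80
Cl	1.75
Ar	1.88
K	2.75
Ca	2.31
Ti	1.87
Cr	1.89
Mn	1.97
Fe	1.94
Co	1.92
Ni	1.63
Cu	1.40
Zn	1.39
Ga	1.87
Ge	2.11
As	1.85
Se	1.90
Br	1.85
Kr	2.02
Sr	2.49
Mo	2.09
Ag	1.72
Cd	1.58
Sn	2.17
Sb	2.06
Te	2.06
I	1.98
Xe	2.16
Cs	3.43
Ba	2.68
W	2.10
Pt	1.75
Au	1.66
Hg	1.55
Pb	2.02
Bi	2.07
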