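# CPK-convention element colors, RGB 0-255.
# Shades follow the widely used Jmol variant of the CPK scheme
# (carbon grey, oxygen red, nitrogen blue, sulfur yellow, ...).
# Unknown symbols fall back to (255, 20, 147) — see chem.FALLBACK_COLOR.
# symbol	red	green	blue
H	255	255	255
He	217	255	255
Li	204	128	255
Be	194	255	0
B	255	181	181
C	144	144	144
N	48	80	248
O	255	13	13
F	144	224	80
Ne	179	227	245
Na	171	92	242
Mg	138	255	0
Al	191	166	166
Si	240	200	160
P	255	128	0
S	255	255	48
Cl	31	240	31
Ar	128	209	227
K	143	64	212
Ca	61	255	0
Ti	191	194	199
Cr	138	153	199
Mn	156	122	199
Fe	224	102	51
Co	240	144	160
Ni	80	208	80
Cu	200	128	51
Zn	125	128	176
Ga	194	143	143
Ge	102	143	143
As	189	128	227
Se	255	161	0
Br	166	41	41
Kr	92	184	209
Sr	0	255	0
Mo	84	181	181
Ag	192	192	192
Cd	255	217	143
Sn	102	128	128
Sb	158	99	181
Te	212	122	0
I	148	0	148
Xe	66	158	176
Cs	87	23	143
Ba	0	201	0
W	33	148	214
Pt	208	208	224
Au	255	209	35
Hg	184	184	208
Pb	87	89	97
Bi	158	79	181
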