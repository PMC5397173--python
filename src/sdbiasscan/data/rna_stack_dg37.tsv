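# RNA:RNA nearest-neighbor stack free energies, dG37 kcal/mol.
# Key: top strand 5'->3' / bottom strand 3'->5' (X.Z and Y.W pairs).
# Watson-Crick stacks: INN-HB (Xia et al. 1998). G.U stacks: Turner 2004.
stack	dG37	source
CC/GG	-3.26	xia1998
CG/GC	-2.36	xia1998
CG/GU	-1.40	turner2004
CU/GG	-2.10	turner2004
CA/GU	-2.11	xia1998
CU/GA	-2.08	xia1998
GC/CG	-3.42	xia1998
GG/CC	-3.26	xia1998
GG/CU	-1.50	turner2004
GU/CG	-2.50	turner2004
GA/CU	-2.35	xia1998
GU/CA	-2.24	xia1998
GC/UG	-2.50	turner2004
GG/UC	-2.10	turner2004
GG/UU	-0.50	turner2004
GU/UG	1.30	turner2004
GA/UU	-1.30	turner2004
GU/UA	-1.40	turner2004
UC/GG	-1.50	turner2004
UG/GC	-1.40	turner2004
UG/GU	0.30	turner2004
UU/GG	-0.50	turner2004
UA/GU	-1.00	turner2004
UU/GA	-0.60	turner2004
AC/UG	-2.24	xia1998
AG/UC	-2.08	xia1998
AG/UU	-0.60	turner2004
AU/UG	-1.40	turner2004
AA/UU	-0.93	xia1998
AU/UA	-1.10	xia1998
UC/AG	-2.35	xia1998
UG/AC	-2.11	xia1998
UG/AU	-1.00	turner2004
UU/AG	-1.30	turner2004
UA/AU	-1.33	xia1998
UU/AA	-0.93	xia1998
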