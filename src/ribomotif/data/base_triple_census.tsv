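# Base-triple census of the eleven reference riboswitch structures.
# Columns: pdb_id, riboswitch_class, residues (triple, reported order),
# wc_pair (the canonical Watson-Crick pair within the triple, empty if none),
# structural context.
1y26	Purine	A23-G46-C53	G46-C53	Interaction between junctions (J1-2 & J2-3)
1y26	Purine	A66-G38-C60	G38-C60	Hairpin loop - hairpin loop interaction (L2 & L3)
2gis	SAM-I	A62-G23-C29	G23-C29	Helix - junction interaction (P2b & J3-4)
2qwy	SAM-II	G8-G42-C23	G42-C23	Helix - hairpin loop interaction
2qwy	SAM-II	U11-A45-U21	A45-U21	Helix - hairpin loop interaction (P2b & L1)
2qwy	SAM-II	U12-A46-U20	A46-U20	Helix - hairpin loop interaction (P2b & L1)
3e5c	SAM-III	A27-G71-G66		Helix - junction interaction (P2 & J3-2)
3e5c	SAM-III	A73-G90-C25	G90-C25	Helix - junction interaction (P1 & J2-4)
3fu2	PreQ1	A16-G11-C31	G11-C31	Helix - hairpin loop interaction (P2 & L2)
3fu2	PreQ1	A28-G5-C18	G5-C18	Helix - hairpin loop interaction (P1 & L3)
3dil	Lysine	A23-G69-A127		Helix - hairpin loop interaction (P2 & L4)
3dil	Lysine	G141-A162-G163		Helix - helix interaction (P1 & P5)
3f2q	FMN	G12-G93-C30	G93-C30	Junction - helix - hairpin loop interaction (J1-2, P2, L5)
2gdi	TPP (prokaryotic)	G19-G42-A47		Helix - junction interaction (P2 & J3-2)
3d2v	TPP (eukaryotic)	A43-A68-U47	A68-U47	Helix - junction interaction (P4 & J2-4)
3pdr	Magnesium	U24-A106-G100	U24-A106	Bulged-out residue - helix interaction (P2 & P5)
3pdr	Magnesium	A46-U138-A139		Interaction within junction (J2-6)
3pdr	Magnesium	C35-U34-U150		Bulged-out residue - helix interaction (P2)
3mxh	Cyclic di-GMP	A95-G14-C93	G14-C93	Bulged-out residue - helix interaction (P1)
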