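variant_id	chrom	pos	ref	alt	gene	hgvs_c	hgvs_p	gnomad_af	clinvar_assertion	hgmd_id	n_carrier_probands	is_null_variant
rs121908038	19	11113293	T	A	LDLR	c.1202T>A	p.Leu401His	NA	likely_pathogenic	NA	3	0
rs137853964	19	11129602	G	A	LDLR	c.2479G>A	p.Val827Ile	0.001006	likely_pathogenic	NA	1	0
rs28942078	19	11113376	G	A	LDLR	c.1285G>A	p.Val429Met	0.000012	pathogenic	NA	2	0
rs539080792	19	11221396	G	A	LDLR	c.1009G>A	p.Glu337Lys	0.000104	uncertain	NA	1	0
rs570942190	19	11113337	C	T	LDLR	c.1246C>T	p.Arg416Trp	0.000024	not_reported	NA	1	0
rs755757866	19	11110730	G	T	LDLR	c.1019G>T	p.Cys340Tyr	0.000008	likely_pathogenic	NA	2	0
rs761954844	19	11110697	G	A	LDLR	c.986G>A	p.Cys329Tyr	0.000016	likely_pathogenic	NA	1	0
rs879254566	19	11105440	T	G	LDLR	c.534T>G	p.Asp178Glu	NA	pathogenic	NA	1	0
rs879254721	19	11107496	G	A	LDLR	c.922G>A	p.Glu308Lys	NA	pathogenic	NA	2	0
rs879254980	19	11116179	G	T	LDLR	c.1672G>T	p.Glu558Ter	NA	pathogenic	NA	1	1
rs879255191	19	11128090	G	A	LDLR	c.2389+5G>A	NA	NA	conflicting	NA	1	0
rs875989907	19	11106666	G	A	LDLR	c.796G>A	p.Asp266Asn	0.000012	pathogenic	NA	1	0
rs879254769	19	11110765	T	C	LDLR	c.1054T>C	p.Cys352Ser	NA	likely_pathogenic	NA	1	0
rs875989894	19	11213415	G	C	LDLR	c.266G>C	p.Cys89Ser	NA	pathogenic	NA	1	0
novel	19	11222252	T	G	LDLR	c.1123T>G	p.Tyr375Asp	NA	not_reported	NA	1	0
rs5742904	2	21006288	G	A	APOB	c.10580G>A	p.Arg3527Gln	0.000275	pathogenic	NA	2	0
rs145164937	2	43832056	C	G	ABCG5	c.293C>G	p.Ala98Gly	0.002223	conflicting	CM169023	1	0
rs138326449	11	116830638	G	A	APOC3	c.55+1G>A	NA	0.002244	conflicting	NA	1	1
rs118204077	8	19955873	C	T	LPL	c.808C>T	p.Arg270Cys	0.0001	pathogenic	CM941054	1	0
rs115855236	17	17820281	C	T	SREBF1	c.422C>T	p.Pro141Leu	0.001210	not_reported	NA	1	0
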