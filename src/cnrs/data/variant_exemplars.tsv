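gene_symbol	exon_id	dna_change	protein_change	transcript	variant_effect
TP53	exon 5	c.524G>A	p.Arg175His	NM_000546	missense
TP53	exon 7	c.743G>A	p.Arg248Gln	NM_000546	missense
TP53	exon 8	c.818G>A	p.Arg273His	NM_000546	missense
TP53	exon 4	c.376-1G>A		NM_000546	splice
TP53	exon 6	c.637C>T	p.Arg213Ter	NM_000546	nonsense
EGFR	exon 21	c.2573T>G	p.Leu858Arg	NM_005228	missense
EGFR	exon 19	c.2235_2249del	p.Glu746_Ala750del	NM_005228	inframe_indel
EGFR	exon 20	c.2369C>T	p.Thr790Met	NM_005228	missense
KRAS	exon 2	c.35G>T	p.Gly12Val	NM_033360	missense
KRAS	exon 2	c.34G>T	p.Gly12Cys	NM_033360	missense
KRAS	exon 3	c.183A>C	p.Gln61His	NM_033360	missense
BRCA1	exon 11	c.3770_3771del	p.Glu1257GlyfsTer9	NM_007294	frameshift
BRCA1	exon 20	c.5266dup	p.Gln1756ProfsTer74	NM_007294	frameshift
BRCA2	exon 11	c.5946del	p.Ser1982ArgfsTer22	NM_000059	frameshift
PIK3CA	exon 10	c.1633G>A	p.Glu545Lys	NM_006218	missense
PIK3CA	exon 21	c.3140A>G	p.His1047Arg	NM_006218	missense
BRAF	exon 15	c.1799T>A	p.Val600Glu	NM_004333	missense
MET	exon 14	c.3028+1G>T		NM_000245	splice
STK11	exon 4	c.580G>T	p.Asp194Tyr	NM_000455	missense
PTEN	exon 5	c.388C>T	p.Arg130Ter	NM_000314	nonsense
NRAS	exon 3	c.181C>A	p.Gln61Lys	NM_002524	missense
IDH1	exon 4	c.395G>A	p.Arg132His	NM_005896	missense
ATM	exon 12	c.1802_1805del	p.Lys601SerfsTer3	NM_000051	frameshift
CDKN2A	exon 2	c.238C>T	p.Arg80Ter	NM_000077	nonsense
APC	exon 16	c.4348C>T	p.Arg1450Ter	NM_000038	nonsense
CTNNB1	exon 3	c.121A>G	p.Thr41Ala	NM_001904	missense
ERBB2	exon 20	c.2313_2324dup	p.Tyr772_Ala775dup	NM_004448	inframe_indel
SMAD4	exon 9	c.1081C>T	p.Arg361Cys	NM_005359	missense
RB1	exon 17	c.1654C>T	p.Arg552Ter	NM_000321	nonsense
FBXW7	exon 9	c.1394G>A	p.Arg465His	NM_033632	missense
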