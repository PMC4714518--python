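gene_name	common_name	chromosome	transposon_note
AC8.10		X	MuDR transposable element
AC8.11		X	MuDR transposable element
AC8.3		X	MuDR transposable element
AC8.4		X	MuDR transposable element
B0491.2.1	sqt-1	II	No obvious transposable elements around
C13B9.4a.1	pdfr-1	III	A short CER9 LTR in an intron
C13B9.4b.1		III	A short CER9 LTR in an intron
C13B9.4c.1		III	A short CER9 LTR in an intron
C18D4.6a		V	Several repeats, a short Tc1A at 3' of the gene
C40A11.10		II	Several repeats around the gene
C44B12.6		IV	Several repeats around the gene
C49C3.12	clec-197	IV	No obvious transposable elements around
C50F4.3	tag-329	V	No obvious transposable elements around
C52E2.6	fbxb-97	II	No obvious transposable elements around
F40D4.13		V	CER15
F41G4.5		X	CER12
F41G4.7		X	CER12
F55D10.3	glit-1	X	No obvious transposable elements in the gene except some repeats around the gene
F57G4.9		V	Repeat Turmoil2, Haringer Family
F58H7.5		IV	CER3 (gypsy)
F58H7.7		IV	CER3 (gypsy)
F59B2.12		III	No obvious transposable elements around
M7.9		IV	No obvious transposable elements around
R09H3.3		X	CER12-I ~ 4 kb downstream
T10D4.4	ins-31	II	Several repeats around the gene
T11F9.10		V	CER15
T11F9.18	srh-1	V	upstream to CER15
W08F4.9	fbxb-14	II	No obvious transposable elements in the gene except some repeats around the gene
Y37H2A.4	fbxa-107	V	CER3 ~ 500 bp upstream
Y38H6C.5	dct-10	V	CER3-I in gene body, Tc4 right downstream
Y43F4A.3		III	CER9
Y53F4B.10		II	Several repeats around the gene
Y56A3A.5	faah-5	III	Several repeats in and around the gene
Y68A4A.13		V	Several repeats in and around the gene
Y77E11A.3		IV	Several repeats around the gene
Y79H2A.4		III	Several Repeat around the gene
ZC15.1		V	CER12-I downstream
ZC15.10		V	CER12-I upstream
ZC15.3		V	CER12
ZK262.8		V	CER8
ZK262.9		V	CER8
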