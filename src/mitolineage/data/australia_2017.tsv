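# Haplogroup definition table "australia_2017": Aboriginal Australian mtDNA
# clades and their spine to the macrohaplogroup roots M / N / R.
#
# Format: one node per line, tab-delimited:
#   label <TAB> parent-label ("-" for the root) <TAB> space-separated variant tokens
# The root is the reference haplotype itself (empty motif); every branch lists
# the mutations acquired on the edge from its parent, in rCRS-relative
# nomenclature (trailing "!" marks a back mutation to the reference state).
#
# Anchoring. The following diagnostics are literature-established:
#   M42   A9156G            (defining mutation of M42; near-stable position)
#   M42a  G12771A, G8251A   (8251 is a well-known mutational hotspot)
#   M42a1 back mutation at 8251 (published M42a genomes lacking 8251A)
#   M42c  C64T, T195C on the A9156G background, and the ABSENCE of G8251A
#   P11   C11288T           (joins the former P4b with the Tasmanian P lineage)
#   S     exactly one mutation step from N (token below is a stand-in)
#   M15/M16 share C16193T (C-tract-adjacent, masked by default in scoring)
#   M15   diagnostic motif of nine mutations
#
# ALL OTHER TOKENS ARE SYNTHETIC STAND-INS: the true diagnostic motifs of
# these clades are published only in supplementary tables that are not part
# of this package. The stand-in tokens are consistent with the packaged
# synthetic reference and exist so that every named clade has a distinct,
# classifiable motif; they must not be quoted as real diagnostics.
ROOT	-
M	ROOT	A1041G C2092T G3115A
N	ROOT	T4216C A5054G C6152T
R	N	G7146A T7861C
M42	M	A9156G
M42a	M42	G12771A G8251A
M42a1	M42a	C1510T G8251A!
M42c	M42	C64T T195C
M42c1	M42c	A2757G
M42c2	M42c	T5027C
M15	M	A1301G C1715T G2831A T3421C A4025G C5186T G6267A T7325C C16193T
M16	M	C16193T T9824C
Q	M	A10241G C11441T
Q1	Q	G2361A
S	N	G8404A
S1	S	T1243C A3756G
S2	S	C5333T G9438A
N13	N	A6755G T8793C
O	N	C3970T G12940A
P	R	A5465G T6719C
P3	P	C8950T G10646A
P4	P	T12346C A13422G
P11	P	C11288T
P11a	P11	G14364A
P11b	P11	T15479C
P5	P	A1736G C9332T
P6	P	G5147A T10910C
P8	P	A2308G C13934T
P12	P	G6023A T14178C
P12a	P12	A15236G
P12b	P12	C15883T
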