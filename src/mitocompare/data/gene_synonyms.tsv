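# alias	canonical
nad1	ND1
nad2	ND2
nad3	ND3
nad4	ND4
nad4l	ND4L
nad5	ND5
nad6	ND6
nd1	ND1
nd2	ND2
nd3	ND3
nd4	ND4
nd4l	ND4L
nd5	ND5
nd6	ND6
ndh1	ND1
cox1	cox1
cox2	cox2
cox3	cox3
coi	cox1
coii	cox2
coiii	cox3
co1	cox1
co2	cox2
co3	cox3
cytb	cob
cob	cob
cytochrome b	cob
atp6	atp6
atp8	atp8
atpase6	atp6
atpase8	atp8
rrns	s-rRNA
rrnl	l-rRNA
12s	s-rRNA
16s	l-rRNA
s-rrna	s-rRNA
l-rrna	l-rRNA
small subunit ribosomal rna	s-rRNA
large subunit ribosomal rna	l-rRNA
trnw	trnW
trnm	trnM
trna-trp	trnW
trna-met	trnM
trnw-uca	trnW
trnm-cau	trnM
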