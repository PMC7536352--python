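psaA	Photosystem I	1
psaB	Photosystem I	1
psaC	Photosystem I	1
psaI	Photosystem I	1
psaJ	Photosystem I	1
ycf3	Photosystem I	1
ycf4	Photosystem I	1
psbA	Photosystem II	1
psbB	Photosystem II	1
psbC	Photosystem II	1
psbD	Photosystem II	1
psbE	Photosystem II	1
psbF	Photosystem II	1
psbH	Photosystem II	1
psbI	Photosystem II	1
psbJ	Photosystem II	1
psbK	Photosystem II	1
psbL	Photosystem II	1
psbM	Photosystem II	1
psbN	Photosystem II	1
psbT	Photosystem II	1
psbZ	Photosystem II	1
petA	Cytochrome b/f complex	1
petB	Cytochrome b/f complex	1
petD	Cytochrome b/f complex	1
petG	Cytochrome b/f complex	1
petL	Cytochrome b/f complex	1
petN	Cytochrome b/f complex	1
atpA	ATP synthase	1
atpB	ATP synthase	1
atpE	ATP synthase	1
atpF	ATP synthase	1
atpH	ATP synthase	1
atpI	ATP synthase	1
ndhA	NADH dehydrogenase	1
ndhB	NADH dehydrogenase	2
ndhC	NADH dehydrogenase	1
ndhD	NADH dehydrogenase	1
ndhE	NADH dehydrogenase	1
ndhF	NADH dehydrogenase	1
ndhG	NADH dehydrogenase	1
ndhH	NADH dehydrogenase	2
ndhI	NADH dehydrogenase	1
ndhJ	NADH dehydrogenase	1
ndhK	NADH dehydrogenase	1
rbcL	RubisCO large subunit	1
ccsA	C-type cytochrome synthesis	1
rpoA	RNA polymerase	1
rpoB	RNA polymerase	1
rpoC1	RNA polymerase	1
rpoC2	RNA polymerase	1
rpl2	Ribosomal proteins (LSU)	1
rpl14	Ribosomal proteins (LSU)	1
rpl16	Ribosomal proteins (LSU)	1
rpl20	Ribosomal proteins (LSU)	1
rpl22	Ribosomal proteins (LSU)	1
rpl23	Ribosomal proteins (LSU)	1
rpl32	Ribosomal proteins (LSU)	1
rpl33	Ribosomal proteins (LSU)	1
rpl36	Ribosomal proteins (LSU)	1
rps2	Ribosomal proteins (SSU)	1
rps3	Ribosomal proteins (SSU)	1
rps4	Ribosomal proteins (SSU)	1
rps7	Ribosomal proteins (SSU)	2
rps8	Ribosomal proteins (SSU)	1
rps11	Ribosomal proteins (SSU)	1
rps12	Ribosomal proteins (SSU)	3
rps14	Ribosomal proteins (SSU)	1
rps15	Ribosomal proteins (SSU)	2
rps16	Ribosomal proteins (SSU)	1
rps18	Ribosomal proteins (SSU)	1
rps19	Ribosomal proteins (SSU)	1
matK	Maturase K	1
accD	Acetyl-CoA carboxylase carboxyltransferase	1
clpP	Clp protease proteolytic subunit	1
cemA	Chloroplast envelope membrane protein	1
orf188	ORFs	2
orf42	ORFs	2
orf56	ORFs	2
ycf1	Hypothetical chloroplast RF	2
ycf15	Hypothetical chloroplast RF	2
ycf2	Hypothetical chloroplast RF	2
ycf68	Hypothetical chloroplast RF	2
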