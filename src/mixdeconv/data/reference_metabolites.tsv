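id	name	formula	keto_acid
pyruvate	pyruvic acid	C3H4O3	1
oxaloacetate	oxaloacetic acid	C4H4O5	1
akg	2-oxoglutaric acid	C5H6O5	1
glyoxylate	glyoxylic acid	C2H2O3	1
kiv	3-methyl-2-oxobutanoic acid	C5H8O3	1
kic	4-methyl-2-oxopentanoic acid	C6H10O3	1
kmv	3-methyl-2-oxopentanoic acid	C6H10O3	1
oxobutanoate	2-oxobutanoic acid	C4H6O3	1
phenylpyruvate	phenylpyruvic acid	C9H8O3	1
hpp	4-hydroxyphenylpyruvic acid	C9H8O4	1
glucose	D-glucose	C6H12O6	0
lactate	lactic acid	C3H6O3	0
citrate	citric acid	C6H8O7	0
succinate	succinic acid	C4H6O4	0
fumarate	fumaric acid	C4H4O4	0
malate	malic acid	C4H6O5	0
glutamine	L-glutamine	C5H10N2O3	0
glutamate	L-glutamic acid	C5H9NO4	0
alanine	L-alanine	C3H7NO2	0
serine	L-serine	C3H7NO3	0
aspartate	L-aspartic acid	C4H7NO4	0
xanthine	xanthine	C5H4N4O2	0
hypoxanthine	hypoxanthine	C5H4N4O	0
inosine	inosine	C10H12N4O5	0
amp	adenosine 5'-monophosphate	C10H14N5O7P	0
atp	adenosine 5'-triphosphate	C10H16N5O13P3	0
nad	nicotinamide adenine dinucleotide	C21H27N7O14P2	0
glutathione	glutathione (reduced)	C10H17N3O6S	0
carnitine	L-carnitine	C7H15NO3	0
palmitate	palmitic acid	C16H32O2	0
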