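# Small drug-like molecules used as ligand templates by the synthetic
# protein-ligand pair generator. All entries are valid, RO5-passing SMILES.
CCO	ethanol
CC(=O)O	acetic-acid
CC(=O)Oc1ccccc1C(=O)O	aspirin
CC(=O)Nc1ccc(O)cc1	paracetamol
CC(C)Cc1ccc(C(C)C(=O)O)cc1	ibuprofen
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
c1ccccc1	benzene
c1ccncc1	pyridine
c1ccc2ccccc2c1	naphthalene
c1ccc2[nH]ccc2c1	indole
c1ccoc1	furan
c1ccsc1	thiophene
c1cnc2[nH]ccc2c1	azaindole
CC(N)Cc1ccccc1	amphetamine
NCCc1ccc(O)c(O)c1	dopamine
NC(Cc1ccc(O)cc1)C(=O)O	tyrosine
NC(Cc1c[nH]c2ccccc12)C(=O)O	tryptophan
OCC1OC(O)C(O)C(O)C1O	glucose
CC(=O)NC1C(O)OC(CO)C(O)C1O	acetylglucosamine
Clc1ccccc1	chlorobenzene
Brc1ccccc1	bromobenzene
Fc1ccc(F)cc1	difluorobenzene
FC(F)(F)c1ccccc1	trifluorotoluene
O=[N+]([O-])c1ccccc1	nitrobenzene
Nc1ccc(S(N)(=O)=O)cc1	sulfanilamide
CC1CCCCN1	methylpiperidine
C1CNCCN1	piperazine
C1CCNCC1	piperidine
C1CCOC1	thf
C1COCCN1	morpholine
O=C1CCCCC1	cyclohexanone
O=C1NC(=O)c2ccccc21	phthalimide
O=c1cc[nH]c(=O)[nH]1	uracil
Cc1cc[nH]c(=O)n1	methylpyrimidinone
Nc1ncnc2[nH]cnc12	adenine
O=C(O)c1ccccc1O	salicylic-acid
O=C(Nc1ccccc1)c1ccccc1	benzanilide
CN(C)CCOC(c1ccccc1)c1ccccc1	diphenhydramine
CC(C)NCC(O)COc1ccccc1	propranolol-fragment
OC(CNC(C)C)c1ccc(O)c(O)c1	isoprenaline
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1	salbutamol
COc1ccc(CCN)cc1	methoxyphenethylamine
COc1ccccc1OC	dimethoxybenzene
Oc1ccc(/C=C/c2cc(O)cc(O)c2)cc1	resveratrol
O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12	quercetin
CC(=O)c1ccccc1	acetophenone
O=Cc1ccccc1	benzaldehyde
OCc1ccccc1	benzyl-alcohol
NC(=O)c1ccccc1	benzamide
N#Cc1ccccc1	benzonitrile
CSc1ccccc1	thioanisole
CS(=O)(=O)c1ccccc1	methylsulfonylbenzene
O=S(=O)(N)c1ccc(Cl)cc1	chlorobenzenesulfonamide
Cc1ccc(S(=O)(=O)Nc2ccccn2)cc1	sulfapyridine-like
c1ccc(-c2ccccc2)cc1	biphenyl
c1ccc(Oc2ccccc2)cc1	diphenylether
c1ccc(Cc2ccccc2)cc1	diphenylmethane
O=C(Cc1ccccc1)Nc1ccccc1	phenylacetanilide
CN1CCN(c2ccccc2)CC1	phenylpiperazine
O=C1c2ccccc2C(=O)N1C	methylphthalimide
CCN(CC)CCNC(=O)c1ccc(N)cc1	procainamide
CCOC(=O)c1ccccc1	ethylbenzoate
COC(=O)c1ccccc1N	methylanthranilate
CC1=CC(=O)CC(C)(C)C1	isophorone
CC(C)=CCCC(C)=CCO	geraniol
CC1CCC(C(C)C)C(O)C1	menthol
Cn1ccnc1	methylimidazole
c1cn[nH]c1	pyrazole
c1cnoc1	isoxazole
c1cnsc1	isothiazole
c1nc2ccccc2[nH]1	benzimidazole
c1nc2ccccc2s1	benzothiazole
c1nc2ccccc2o1	benzoxazole
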