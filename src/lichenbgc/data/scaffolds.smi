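CC(=O)Oc1ccccc1C(=O)O	aspirin
Cn1cnc2c1c(=O)n(C)c(=O)n2C	caffeine
CC(C)Cc1ccc(cc1)C(C)C(=O)O	ibuprofen
CC(=O)Nc1ccc(O)cc1	paracetamol
COc1ccc2cc(ccc2c1)C(C)C(=O)O	naproxen
Cc1cc(no1)NS(=O)(=O)c1ccc(N)cc1	sulfamethoxazole
OC(=O)c1cn(C2CC2)c2cc(N3CCNCC3)c(F)cc2c1=O	ciprofloxacin
OCC(NC(=O)C(Cl)Cl)C(O)c1ccc(cc1)[N+]([O-])=O	chloramphenicol
Cc1ncc([N+]([O-])=O)n1CCO	metronidazole
COc1cc(Cc2cnc(N)nc2N)cc(OC)c1OC	trimethoprim
NNC(=O)c1ccncc1	isoniazid
CN1CCCC1c1cccnc1	nicotine
COc1ccc2nccc(C(O)C3CC4CCN3CC4C=C)c2c1	quinine
CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O	warfarin
CC1(C)SC2C(NC(=O)Cc3ccccc3)C(=O)N2C1C(=O)O	penicillin-g
OC(=O)Cc1ccccc1Nc1c(Cl)cccc1Cl	diclofenac
NS(=O)(=O)c1cc(C(=O)O)c(NCc2ccco2)cc1Cl	furosemide
CC(C)NCC(O)COc1ccc(CC(N)=O)cc1	atenolol
CC(C)NCC(O)COc1cccc2ccccc12	propranolol
CCN(CC)CC(=O)Nc1c(C)cccc1C	lidocaine
CC(C)(C)NCC(O)c1ccc(O)c(CO)c1	salbutamol
CC1=C(CSCCNC(=NC)NC#N)N=CN1	cimetidine
CCC(CO)NCCNC(CC)CO	ethambutol
Nc1ccc(cc1)S(=O)(=O)c1ccc(N)cc1	dapsone
CC1COc2c(N3CCN(C)CC3)c(F)cc3c(=O)c(cn1c23)C(=O)O	levofloxacin
COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1	indomethacin
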