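# Built-in technique query set, one named query per line (shorthand <TAB> query).
# Every query is conjoined at load time with (METHODS:"mass spectrometry" OR METHODS:"MS").
APCI	(METHODS:APCI OR METHODS:"atmospheric pressure chemical ionization" OR METHODS:"atmospheric pressure chemical ionisation")
EI	(METHODS:EI OR METHODS:"electron ionization" OR METHODS:"electron ionisation" OR METHODS:"electron impact")
ESI	(METHODS:ESI OR METHODS:"electrospray ionization" OR METHODS:"electrospray ionisation")
DART	(METHODS:"DART" OR METHODS:"direct analysis in real time")
DIOS	(METHODS:"DIOS" OR METHODS:"desorption/ionization on silicon" OR METHODS:"desorption/ionisation on silicon")
FAB	(METHODS:FAB OR METHODS:"fast atom bombardment")
LDI	(METHODS:"LDI" OR METHODS:"laser desorption/ionization" OR METHODS:"laser desorption/ionisation") AND NOT (METHODS:"MALDI" OR METHODS:"SALDI" OR METHODS:"SELDI" OR METHODS:"matrix-assisted" OR METHODS:"surface assisted" OR METHODS:"suface enhaced")
NALDI	(METHODS:"NALDI" OR METHODS:"nano-assisted laser desorption")
MALDI	(METHODS:MALDI OR METHODS:"matrix-assisted laser desorption/ionization" OR METHODS:"matrix-assisted laser desorption/ionisation")
MALDI-small-molecules	("small molecule" OR "small molecules") AND(METHODS:MALDI OR METHODS:"matrix-assisted laser desorption/ionization" OR METHODS:"matrix-assisted laser desorption/ionisation")
NIMS	(METHODS:"NIMS" OR METHODS:"nanostructure-initiator" OR METHODS:"nanostructure imaging")
NIMS-imaging	(METHODS:"NIMS" AND METHODS:"nanostructure imaging")
NIMS-initiator	(METHODS:"NIMS" AND METHODS:"nanostructure-initiator")
SALDI	(METHODS:"SALDI" OR METHODS:"surface assisted")
SELDI	(METHODS:SELDI OR METHODS:"surface-enhanced laser desorption/ionization" OR METHODS:"surface-enhanced laser desorption/ionisation")
SIMS	(METHODS:SIMS OR METHODS:"secondary ion")
SIMS-imaging	(METHODS:"SIMS imaging" OR METHODS:"secondary ion imaging")
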