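# Synthetic reconstruction of the blocker comparison set (not a deposited data set).
# PQ0-PQ5: octa(ethylene glycol) bis-quaternary-ammonium blockers assembled from their
# described composition (backbone: -CH2CH2(OCH2CH2)7- joining two QA groups; QA groups:
# PQ0 trimethylammonium, PQ1 N-methylpyrrolidinium, PQ2 N-methylpiperidinium,
# PQ3 triethylammonium, PQ4 N-methylazepanium, PQ5 N-methyldipropylammonium).
# kd_uM for PQ0-PQ5 are the reported single-channel dissociation constants; kd_uM for
# the non-PEG comparators are approximate literature values for open-channel block of
# the muscle AChR, included only to populate the affinity axis of the comparison table.
# The tubocurarine entry is a formula-correct (C37H41N2O6+) bisbenzylisoquinoline
# reconstruction of the macrocycle.
name	pq_class	kd_uM	smiles
PQ0	PEG-based	9.0	C[N+](C)(C)CCOCCOCCOCCOCCOCCOCCOCC[N+](C)(C)C
PQ1	PEG-based	3.0	C[N+]1(CCOCCOCCOCCOCCOCCOCCOCC[N+]2(C)CCCC2)CCCC1
PQ2	PEG-based	0.08	C[N+]1(CCOCCOCCOCCOCCOCCOCCOCC[N+]2(C)CCCCC2)CCCCC1
PQ3	PEG-based	0.17	CC[N+](CC)(CC)CCOCCOCCOCCOCCOCCOCCOCC[N+](CC)(CC)CC
PQ4	PEG-based	0.19	C[N+]1(CCOCCOCCOCCOCCOCCOCCOCC[N+]2(C)CCCCCC2)CCCCCC1
PQ5	PEG-based	0.12	CCC[N+](C)(CCC)CCOCCOCCOCCOCCOCCOCCOCC[N+](C)(CCC)CCC
(+)-tubocurarine	non-PEG-based	0.2	C[N+]1(C)CCc2cc(OC)c3cc2C1Cc1ccc(Oc2cc5c(c(O)c2OC)CCN(C)C5Cc2ccc(O)c(O3)c2)cc1
MK-801	non-PEG-based	7.0	CC12Cc3ccccc3C(c3ccccc31)N2
physostigmine	non-PEG-based	50.0	CNC(=O)Oc1ccc2c(c1)C1(C)CCN(C)C1N2C
lamotrigine	non-PEG-based	100.0	Nc1nnc(-c2cccc(Cl)c2Cl)c(N)n1
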