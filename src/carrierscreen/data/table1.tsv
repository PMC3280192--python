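drug	pool_hits	robot_conc_uM	robot_hits	indirect_hits	verification	verified_genes	competitor_protects	lipinski_pass	raw_pool	raw_robot	raw_indirect
Aminopterin		2	NRT1;FEN2	CTR1	partial	NRT1;CTR1	not_tested	fail		nrt1Δ, fen2Δ	ctr1Δ
Ammonium pyrrolidine dithiocarbamate		20		PCA1	not_tested		not_tested	pass			pca1Δ
Artesunate		100	FEN2@2	CCH1@2;MID1@2	not_tested		not_tested	pass		fen2Δ (2*σ)	cch1Δ, mid1Δ (2*σ)
Bay 11-7985		10	FUI1		not_tested		not_tested	pass		fui1Δ	
Benzbromarone		28	FUI1		not_tested		not_tested	fail	None	fui1Δ	
Canavanine	CAN1	5	CAN1		confirmed	CAN1	pass	fail	can1Δ	can1Δ	
Cantharidin		30	FEN2@2.5;SNQ2@2.5	CCH1@2.5;MID1@2.5;PHO89@2.5	partial	FEN2;PHO89	not_tested	pass		fen2Δ, snq2Δ (2.5*σ)	cch1Δ, mid1Δ, pho89Δ (2.5*σ)
Cisplatin		50	FCY2;LEM3;FAT1@2;FPS1@2;HNM1@2		partial	FCY2	not_tested	pass		fcy2Δ, lem3Δ, (fat1Δ, fps1Δ, hnm1Δ 2*σ)	
Clotrimazole		25	ITR1	FTR1;FET3	not_tested		not_tested	fail		itr1Δ	ftr1Δ fet3Δ
3,4-Dichloroisocoumarin		8			not_tested		not_tested	pass		None	
Diphenyleneiodonium chloride	NRT1	8	NRT1		confirmed	NRT1	pass	pass	nrt1Δ	nrt1	
Fluconazole		100	ITR1;FCY2	FTR1;FET3	not_tested		not_tested	pass		itr1Δ fcy2Δ	ftr1Δ fet3Δ
5-Fluorocytosine		158	FCY2		confirmed	FCY2	not_tested	pass		fcy2	
5-Fluorouracil		158	FCY2	FEN2	confirmed	FCY2;FEN2	not_tested	pass		fcy2Δ	fen2Δ
Iodoacetamide		20	MAL11@2.5		solid_only		not_tested	pass		mal11Δ (2.5*σ)	
Ketoconazole		80	ITR1;FAT1		not_tested		not_tested	fail		itr1Δ fat1Δ	
Methotrexate		100	NRT1		confirmed	NRT1	pass	fail		nrt1Δ	
Mitoxantrone		75	AGP1		not_tested		not_tested	fail		agp1	
1,10-Phenanthroline		14		CTR1	not_tested		not_tested	pass			ctr1Δ
N-Phenylanthranilic acid		100			not_tested		not_tested	pass		None	
Protoporphyrin		600	AGP1		not_tested		not_tested	fail		agp1Δ	
Tamoxifen		730			not_tested		not_tested	fail		None	
Tetraethylthiuram disulfide		10		PDR5@2	not_tested		not_tested	fail			pdr5Δ (2*σ)
Tunicamycin		4	LEM3;DNF2;QDR2	PCA1;PHO89	confirmed	LEM3;DNF2;QDR2;PCA1;PHO89	not_tested	fail		lem3Δ dnf2Δ qdr2Δ	pca1Δ pho89Δ
Vanillylmandelic acid		647			not_tested		not_tested	pass		None	
ZM 39923		14			not_tested		not_tested	fail		None	
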