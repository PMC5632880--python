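pair	mirna	log2_fc	p_value
sham_vs_tac4w	mmu-miR-345-3p	6.67582	0.015490
sham_vs_tac4w	mmu-miR-532-5p	4.09083	9.83e-09
sham_vs_tac4w	mmu-miR-709	3.70383	0.000961
sham_vs_tac4w	mmu-miR-181b-5p	3.70383	0.000961
sham_vs_tac4w	mmu-miR-133a-3p	3.17332	0.011587
sham_vs_tac4w	mmu-miR-690	3.00339	0.021268
sham_vs_tac4w	mmu-miR-133b-3p	3.00339	0.021268
sham_vs_tac4w	mmu-miR-696	2.91028	0.001289
sham_vs_tac4w	mmu-miR-122-5p	2.86861	5.72e-18
sham_vs_tac4w	mmu-miR-181a-5p	2.81075	0.038716
sham_vs_tac4w	mmu-miR-140-3p	2.70383	0.004118
sham_vs_tac4w	mmu-miR-145a-3p	-1.06684	0.00531
sham_vs_tac4w	mmu-miR-200b-3p	-2.9964	0.021703
sham_vs_tac8w	mmu-miR-6538	3.54852	5.29e-45
sham_vs_tac8w	mmu-miR-299a-5p	3.21129	0.010257
sham_vs_tac8w	mmu-miR-199a-5p	3.04141	0.019076
sham_vs_tac8w	mmu-miR-5126	3.04141	0.019076
sham_vs_tac8w	mmu-miR-532-5p	3.04136	0.000584
sham_vs_tac8w	mmu-miR-148a-3p	2.87806	5.57e-18
sham_vs_tac8w	mmu-miR-208a-3p	2.74182	0.003498
sham_vs_tac8w	mmu-miR-7225-5p	2.04169	0.01827
sham_vs_tac8w	mmu-miR-133b-3p	1.82293	3.62e-17
sham_vs_tac8w	mmu-miR-28a-3p	1.62637	0.16591
sham_vs_tac8w	mmu-miR-146a-5p	1.50101	0.008471
sham_vs_tac8w	mmu-miR-709	1.48215	1.64e-09
sham_vs_tac8w	mmu-miR-34c-5p	-1.04088	0.000366
sham_vs_tac8w	mmu-miR-696	-1.35071	0.019921
sham_vs_tac8w	mmu-miR-345-3p	-1.72393	0.000356
sham_vs_tac8w	mmu-miR-132-3p	-2.47141	3.24e-88
sham_vs_tac8w	mmu-miR-181a-2-3p	-2.95879	0.024148
sham_vs_tac8w	mmu-miR-200b-3p	-7.08725	0.004443
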