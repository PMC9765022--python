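# Published benchmark of spike-in absolute quantification on the 8-species
# ZymoBIOMICS DNA mock community: expected percent of cells (manufacturer),
# percentages predicted from three spike-in pools, and the read-count
# relative-abundance baseline.
species	gc_pct	expected_pct	pool1_pct	pool1_sd	pool2_pct	pool2_sd	pool3_pct	pool3_sd	relabund_pct
Bacillus_subtilis	43.9	10.3	9.508	0.017	9.526	0.011	9.511	0.017	4.788
Enterococcus_faecalis	37.5	14.6	14.532	0.027	14.529	0.023	14.420	0.030	10.967
Escherichia_coli	46.7	8.5	9.068	0.030	9.065	0.016	9.142	0.029	24.351
Lactobacillus_fermentum	52.4	21.6	19.671	0.081	19.689	0.116	19.806	0.076	3.709
Listeria_monocytogenes	38.0	13.9	12.438	0.023	12.446	0.040	12.330	0.022	3.389
Pseudomonas_aeruginosa	66.2	6.1	6.422	0.037	6.429	0.017	6.491	0.030	20.765
Salmonella_enterica	52.2	8.7	9.215	0.034	9.211	0.018	9.293	0.034	22.083
Staphylococcus_aureus	32.9	15.2	14.511	0.054	14.448	0.061	14.386	0.042	6.812
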