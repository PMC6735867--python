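genome_id	group	assembly_status	size_mb	gc_pct	n_major_strains	source
Cj1_Dg_nod	Eurasian	draft	8.526	68.24	2	whole_nodule
Cj1_Dg_vc	Eurasian	draft	5.044	69.94	1	vesicle_cluster
Cm1_Cm_nod	Eurasian	draft	4.953	70.22	1	whole_nodule
Cm1_Dg_nod	Eurasian	draft	9.779	69.28	2	whole_nodule
Cm1_Dg_vc	Eurasian	draft	5.069	69.82	1	vesicle_cluster
Cv1_Ct_nod	NorthAmerican	draft	5.499	68.07	1	whole_nodule
Crpng1_Ca_nod	Southern	draft	5.046	67.50	1	whole_nodule
Dd1_Dg_nod	NorthAmerican	draft	5.435	67.80	1	whole_nodule
Dd1_Dg_vc	NorthAmerican	draft	5.573	67.97	1	vesicle_cluster
Dg1_Dg_vc	Eurasian	complete	5.323	70.04	1	vesicle_cluster
Dg1_Dg_nod1	Eurasian	draft	4.888	70.14	1	whole_nodule
Dg1_Dg_nod2	Eurasian	draft	5.548	69.32		whole_nodule
Dg1_Cn_nod	Eurasian	draft	5.191	69.55		whole_nodule
Dg2_Dg_vc	NorthAmerican	draft	5.929	67.90	2	vesicle_cluster
BMG5.1	Eurasian	draft				isolate
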