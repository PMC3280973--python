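comparison	group_pos	group_neg	rest_pos	rest_neg	test
t_all_vs_bcp_all	0	109	65	657	chi_square
hyperdiploid	5	155	55	422	chi_square
etv6_runx1	27	115	22	349	chi_square
bcr_abl1	6	17	52	573	chi_square
mll_rearranged	0	17	55	577	fisher
other_subgroup	13	167	38	304	chi_square
subgroup_unknown	14	186	51	471	chi_square
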