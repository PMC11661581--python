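category,item,points
family_history,first_degree_premature_cvd,1
family_history,first_degree_high_ldl,1
family_history,first_degree_xanthoma_or_arcus,2
family_history,child_high_ldl,2
clinical_history,premature_chd,2
clinical_history,premature_cerebral_peripheral,1
physical_exam,tendon_xanthomas,6
physical_exam,arcus_cornealis_under_45,4
ldl_c,ldl_ge_8_5,8
ldl_c,ldl_6_5_to_8_4,5
ldl_c,ldl_5_0_to_6_4,3
ldl_c,ldl_4_0_to_4_9,1
dna,causal_mutation,8
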