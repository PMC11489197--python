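# Worked case: adult SPG7 with bilateral T2 hyperintensity of the
# dentate nuclei.  The case asserts only the dentate finding; the
# atrophy pattern is not stated, so the differential legitimately spans
# both SPG7-bearing branches of the tree.
patient_id: fig4_spg7
mri_dn_t2_hyperintensity: present
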