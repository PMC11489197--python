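# Worked case: ARSACS with selective atrophy of the superior vermis;
# inferior vermis and cerebellar hemispheres unremarkable.  Only the
# asserted imaging findings are set; everything else is left unknown.
patient_id: fig3_arsacs
mri_vermis_superior_atrophy: present
mri_vermis_inferior_atrophy: absent
mri_hemispheric_atrophy: absent
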