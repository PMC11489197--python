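# Worked case: adult SCA6 with "pure" cerebellar atrophy -- concomitant
# superior vermis and hemispheric involvement, with inferior vermis
# volume loss less marked although present.  Only the asserted imaging
# findings are set; everything else (including onset age, which the case
# does not state) is left unknown.
patient_id: fig2_sca6
mri_vermis_superior_atrophy: present
mri_vermis_inferior_atrophy: present
mri_hemispheric_atrophy: present
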