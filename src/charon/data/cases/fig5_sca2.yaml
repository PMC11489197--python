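# Worked case: adult SCA2 with a "Hot Cross Bun" sign (T2
# hyperintensity of transverse pontine fibers and median raphe).  Only
# the asserted imaging finding is set; everything else is left unknown.
patient_id: fig5_sca2
mri_hcb_sign: present
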