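category,band_0_5,band_6_12
conventional_tablet,1,3
scored_tablet,1,3
capsule_hard,1,3
capsule_softgel,1,3
dispersible_tablet,3,3
orodispersible_tablet,3,3
oral_liquid,3,3
powder_for_oral_liquid,3,3
granules_minitablets,3,3
suppository,3,3
injection,2,2
topical_semisolid,3,3
unknown,0,0
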