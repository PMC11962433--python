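impact_category,damage_species_yr
TAP,5.0E-10
GWP_freshwater,6.8E-10
GWP_terrestrial,2.5E-08
FETP,4.0E-11
METP,2.8E-08
TETP,6.0E-11
FEP,9.0E-12
MEP,4.0E-12
LOP,2.0E-09
EOFP,3.0E-10
WCP_aquatic,5.0E-12
WCP_terrestrial,1.5E-09
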