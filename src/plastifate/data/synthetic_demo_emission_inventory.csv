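emission_set,stage,polymer_id,shape,size_um,mass_kg,compartment
plp_pfn,granulate_production,PLA,sphere,100,2.0E-06,marine
plp_pfn,wet_processing,PLA,fiber,100,5.0E-05,marine
plp_pfn,laundry,PLA,fiber,100,3.0E-05,marine
plp_pfn,end_of_life,PLA,fiber,100,2.0E-05,marine
high,granulate_production,PLA,sphere,100,2.0E-06,marine
high,wet_processing,PLA,fiber,100,5.0E-05,marine
high,laundry,PLA,fiber,100,3.0E-05,marine
high,end_of_life,PLA,fiber,100,2.0E-05,marine
high,end_of_life_fragmentation,PLA,fiber,100,1.5E-01,marine
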