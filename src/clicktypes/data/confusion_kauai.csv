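,false_killer_whale,rough_toothed_dolphin,short_finned_pilot_whale_1,short_finned_pilot_whale_2,bottlenose_melon_headed,blainville_beaked_whale,cuvier_beaked_whale,stenellid_1,stenellid_2,kogia,noise
false_killer_whale,242,14,1,0,0,0,0,0,0,0,2
rough_toothed_dolphin,20,4450,38,7,29,0,1,44,9,0,4
short_finned_pilot_whale_1,5,9,212,0,4,0,0,0,0,0,0
short_finned_pilot_whale_2,2,7,1,24,0,0,0,0,1,0,1
bottlenose_melon_headed,0,3,5,0,182,0,0,2,0,0,0
blainville_beaked_whale,0,0,0,1,0,90,0,0,0,0,0
cuvier_beaked_whale,0,0,0,0,0,0,0,0,0,0,0
stenellid_1,0,4,1,3,8,0,0,1199,0,0,4
stenellid_2,0,1,0,1,1,0,1,0,179,0,0
kogia,0,0,0,0,0,0,0,0,0,52,0
noise,50,12,10,28,2,1,0,9,0,5,1088
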