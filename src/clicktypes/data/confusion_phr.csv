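,false_killer_whale,rough_toothed_dolphin,short_finned_pilot_whale_1,short_finned_pilot_whale_2,bottlenose_melon_headed,blainville_beaked_whale,cuvier_beaked_whale,stenellid_1,stenellid_2,kogia,noise
false_killer_whale,83,1,2,0,0,0,0,0,0,0,0
rough_toothed_dolphin,11,754,21,1,4,0,0,7,0,2,1
short_finned_pilot_whale_1,11,0,58,0,2,0,0,1,0,0,0
short_finned_pilot_whale_2,1,1,0,8,1,0,0,0,0,0,0
bottlenose_melon_headed,0,33,0,0,254,0,0,20,0,0,0
blainville_beaked_whale,0,0,8,7,2,1986,0,1,0,2,2
cuvier_beaked_whale,0,0,4,7,1,1,531,0,1,0,1
stenellid_1,0,4,2,0,14,0,0,344,0,0,0
stenellid_2,0,0,0,0,0,0,0,0,24,0,0
kogia,0,0,0,0,0,0,0,0,0,13,0
noise,132,3,4,8,1,3,0,8,0,8,1187
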