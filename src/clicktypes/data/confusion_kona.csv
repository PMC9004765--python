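,false_killer_whale,rough_toothed_dolphin,short_finned_pilot_whale_1,short_finned_pilot_whale_2,bottlenose_melon_headed,blainville_beaked_whale,cuvier_beaked_whale,stenellid_1,stenellid_2,kogia,noise
false_killer_whale,285,0,25,8,1,0,0,0,0,0,5
rough_toothed_dolphin,1,389,19,14,2,1,0,33,3,0,6
short_finned_pilot_whale_1,45,23,885,5,6,2,0,14,2,0,6
short_finned_pilot_whale_2,6,3,5,446,0,0,0,2,0,0,1
bottlenose_melon_headed,0,14,16,11,161,1,0,3,7,0,0
blainville_beaked_whale,0,0,0,1,1,218,1,3,0,1,2
cuvier_beaked_whale,0,0,0,0,0,0,5,0,0,0,1
stenellid_1,1,24,19,17,35,3,5,5713,16,1,6
stenellid_2,0,1,0,1,0,0,0,0,727,0,0
kogia,0,0,0,0,1,0,0,0,0,249,0
noise,250,10,25,47,8,15,0,67,19,15,3662
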