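sample,skater_id,distance,N_altitude,N_ice_temp,N_race_freq
1,A,500,-13,0,-10
2,B,500,-34,44,4
3,C,500,-16,19,-9
4,D,500,-18,-6,0
5,E,1000,-89,15,-4
6,D,1000,-78,-16,-2
7,F,1000,-81,36,-109
8,E,1500,-141,80,-13
9,G,1500,-105,-28,-196
10,D,1500,-128,63,-31
11,F,1500,-138,29,-99
12,H,1500,-78,-121,-122
13,F,3000,-98,134,-221
14,G,3000,-214,-510,-187
15,H,3000,-270,-399,-494
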