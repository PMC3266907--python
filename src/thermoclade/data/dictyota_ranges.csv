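species,n,lat_range,lon_range,max_c,mean_c,min_c,max_range_c
Dictyota cf. caribaea,3,3.6,3.3,31.0,28.5,26.1,6.6
Dictyota ciliolata,305,66.8,308.5,29.9,27.5,24.9,21.1
Dictyota crenulata#1,25,21.1,30.9,29.4,25.9,22.6,16.3
Dictyota crenulata#2,18,18.1,11.2,26.2,23.6,21.5,9.5
Dictyota crenulata#3,64,23.0,73.2,29.6,27.7,25.9,11.5
Dictyota crenulata#4,14,1.1,2.9,23.8,21.2,18.9,6.1
Dictyota cymatophila,13,0.9,2.3,23.8,21.3,18.9,5.9
Dictyota implexa,111,36.3,116.4,25.9,21.1,17.1,22.3
Dictyota mertensii,15,4.9,15.3,30.2,27.9,26.3,8.3
Dictyota sandvicensis,13,0.4,0.5,27.1,25.7,24.4,3.4
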