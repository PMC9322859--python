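threat,max_distance_km,weight,decay
cultivated,3,0.7,linear
construction,10,1,exponential
national_road,2,0.8,linear
provincial_road,2,0.8,linear
railway,2,0.8,linear
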