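from_class,cultivated,woodland,grassland,waters,construction,unused
cultivated,45189.71,437.62,1840.31,181.06,1945.30,18.46
woodland,183.38,22410.22,367.73,10.41,49.10,9.39
grassland,1063.22,434.71,27107.45,38.64,92.82,15.80
waters,131.65,7.38,35.87,1043.12,29.92,3.16
construction,316.02,6.68,17.19,6.30,4026.26,0.32
unused,10.65,4.91,12.96,15.55,3.78,112.55
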