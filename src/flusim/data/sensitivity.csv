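class,habitat_suitability,cultivated,construction,national_road,provincial_road,railway
cultivated,0.6,0.3,1,0.4,0.4,0.3
woodland,1,0.8,0.8,0.6,0.6,0.5
grassland,1,0.7,0.7,0.4,0.3,0.2
waters,0.8,0.5,0.9,0.5,0.4,0.4
construction,0,0,0,0,0,0
unused,0,0,0,0,0,0
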