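locus_id,wolf,dog
rs22103787,0.926,0.444
rs22835438,1.000,0.991
rs23249721,1.000,1.000
rs23608542,0.969,0.991
rs23882488,1.000,0.991
rs24163825,0.990,1.000
rs24189603,1.000,0.972
rs24198287,1.000,1.000
rs24355642,0.938,1.000
rs24383001,0.979,1.000
rs24863098,1.000,1.000
rs9089629,1.000,0.991
rs9159232,1.000,0.981
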