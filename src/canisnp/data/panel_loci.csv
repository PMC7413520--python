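locus_id,allele_a,allele_b
rs22103787,C,T
rs22835438,G,T
rs23249721,C,T
rs23608542,G,A
rs23882488,G,T
rs24163825,G,T
rs24189603,G,A
rs24198287,G,A
rs24355642,C,T
rs24383001,C,T
rs24863098,C,A
rs9089629,G,A
rs9159232,G,A
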