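locus_id,population,n,hom_a,het,hom_b,p_a,p_b,between_diff
rs22835438,wolf,80,1.000,0.000,0.000,1.000,0.000,0.889
rs22835438,dog,90,0.056,0.111,0.833,0.111,0.889,0.889
rs23249721,wolf,80,0.000,0.038,0.962,0.019,0.981,0.820
rs23249721,dog,90,0.756,0.167,0.078,0.839,0.161,0.820
rs23608542,wolf,80,0.886,0.089,0.025,0.930,0.070,0.814
rs23608542,dog,90,0.033,0.167,0.800,0.117,0.883,0.814
rs23882488,wolf,80,0.000,0.025,0.975,0.013,0.988,0.694
rs23882488,dog,90,0.552,0.310,0.138,0.707,0.293,0.694
rs24163825,wolf,80,0.000,0.113,0.888,0.056,0.944,0.872
rs24163825,dog,90,0.878,0.100,0.022,0.928,0.072,0.872
rs24189603,wolf,80,0.000,0.152,0.848,0.076,0.924,0.852
rs24189603,dog,90,0.878,0.100,0.022,0.928,0.072,0.852
rs24198287,wolf,80,0.855,0.145,0.000,0.928,0.072,0.853
rs24198287,dog,90,0.025,0.100,0.875,0.075,0.925,0.853
rs24355642,wolf,80,1.000,0.000,0.000,1.000,0.000,0.826
rs24355642,dog,90,0.090,0.169,0.742,0.174,0.826,0.826
rs24383001,wolf,80,0.950,0.050,0.000,0.975,0.025,0.829
rs24383001,dog,90,0.022,0.247,0.730,0.146,0.854,0.829
rs24863098,wolf,80,0.000,0.000,1.000,0.000,1.000,0.640
rs24863098,dog,90,0.483,0.315,0.202,0.640,0.360,0.640
rs9089629,wolf,80,0.925,0.075,0.000,0.963,0.038,0.796
rs9089629,dog,90,0.044,0.244,0.711,0.167,0.833,0.796
rs9159232,wolf,80,1.000,0.000,0.000,1.000,0.000,0.685
rs9159232,dog,90,0.180,0.270,0.551,0.315,0.685,0.685
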