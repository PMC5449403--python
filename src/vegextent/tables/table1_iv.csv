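species,cluster,I,I-O,Oil,O-II,II,10m,30m,50m,100m,300m,500m,800m,1000m
Kalidium gracile,1,0.133,0.085,0.206,0.095,0.442,0.076,0.168,0.182,0.153,0.179,0.180,0.183,0.245
Leymus secalinus,1,0.089,0.303,0.097,0.214,0.054,0.337,0.314,0.391,0.134,0.094,0.275,0.180,0.241
Phragmites australis,1,0.622,0.236,0.518,0.406,0.462,0.482,0.581,0.558,0.263,0.180,0.127,0.092,0.089
Kalidium foliatum,2,0.081,0.085,0.097,0.077,0.042,0.122,0.126,0.228,0.384,0.491,0.477,0.540,0.382
Scorzonera sinensis,2,0.074,0.234,0.082,0.209,0.000,0.280,0.306,0.250,0.422,0.379,0.384,0.400,0.355
Achnatherum splendens,3,0.000,0.057,0.000,0.000,0.000,0.000,0.000,0.000,0.035,0.035,0.094,0.096,0.180
Galium verum,3,0.000,0.000,0.000,0.000,0.000,0.000,0.022,0.020,0.060,0.059,0.113,0.081,0.113
Nitraria sibirica,3,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.000,0.068,0.064,0.055,0.058,0.062
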