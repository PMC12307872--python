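# Parkes (consensus) error grid, type 2 diabetes, zone polygons in mg/dL.
# Axes: x = reference glucose, y = predicted glucose, domain [0, 550]^2.
# Provenance: consensus error grid of Parkes et al., Diabetes Care 23(8), 2000;
# real-coordinate digitisation lineage of Pfutzner et al., J Diabetes Sci
# Technol 7(5), 2013, as transcribed in open-source error-grid implementations.
# Each (zone, segment) pair is one closed polygon; vertices in order.
zone,segment,x,y
A,0,0,0
A,0,50,0
A,0,50,30
A,0,90,80
A,0,330,230
A,0,550,450
A,0,550,550
A,0,440,550
A,0,230,330
A,0,30,50
A,0,0,50
B,upper,0,50
B,upper,30,50
B,upper,230,330
B,upper,440,550
B,upper,280,550
B,upper,30,60
B,upper,0,60
B,lower,50,0
B,lower,90,0
B,lower,260,130
B,lower,550,250
B,lower,550,450
B,lower,330,230
B,lower,90,80
B,lower,50,30
C,upper,0,60
C,upper,30,60
C,upper,280,550
C,upper,125,550
C,upper,35,90
C,upper,25,80
C,upper,0,80
C,lower,90,0
C,lower,250,0
C,lower,250,40
C,lower,410,110
C,lower,550,160
C,lower,550,250
C,lower,260,130
D,upper,0,80
D,upper,25,80
D,upper,35,90
D,upper,125,550
D,upper,50,550
D,upper,35,200
D,upper,0,200
D,lower,250,0
D,lower,550,0
D,lower,550,160
D,lower,410,110
D,lower,250,40
E,upper,0,200
E,upper,35,200
E,upper,50,550
E,upper,0,550
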