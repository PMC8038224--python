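movement,axis,metric,s1,s2,s3,s4,s5,s6,s7,s8,s9
bending,y,r,0.97,0.98,0.96,0.97,0.98,,0.96,0.35,0.98
bending,y,r2,0.94,0.95,0.93,0.93,0.96,,0.92,0.12,0.96
lateroflexion,x,r,0.94,0.93,0.95,0.95,0.94,,0.85,0.32,0.92
lateroflexion,x,r2,0.89,0.87,0.91,0.90,0.88,,0.72,0.10,0.84
rotation,z,r,0.63,0.23,0.84,0.84,0.81,,0.76,0.38,0.92
rotation,z,r2,0.40,0.06,0.70,0.70,0.65,,0.58,0.15,0.84
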