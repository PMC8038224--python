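movement,axis,s1,s2,s3,s4,s5,s6,s7,s8,s9
bending,x,12.5,5.00,10.7,4.49,7.09,,5.24,17.2,4.84
bending,y,8.95,8.65,9.85,8.56,10.4,,21.1,9.31,6.17
bending,z,6.49,3.91,5.66,3.15,5.87,,6.70,9.64,2.61
lateroflexion,x,17.2,10.9,12.5,7.12,13.4,,19.5,31.3,11.9
lateroflexion,y,23.7,11.2,11.7,6.83,16.6,,13.2,19.5,11.7
lateroflexion,z,11.3,8.88,10.4,3.48,9.83,,8.73,24.0,6.92
rotation,x,2.98,2.55,3.27,3.89,6.07,,5.15,18.9,2.73
rotation,y,4.28,4.10,3.73,4.06,6.26,,6.05,21.5,4.33
rotation,z,5.01,5.73,4.41,4.12,6.32,,6.90,12.8,4.87
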