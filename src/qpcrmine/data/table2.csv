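peg,proline,feature,mean,se,letters
0,0,TPS27,1,0,f
0,0,L3H,1,0,f
0,0,TPS2,1,0,b
0,0,TPS1,1,0,i
0,0,OMT,1,0,hi
0,0,GDH1,1,0,gh
0,5,TPS27,0.84,0.012,f
0,5,L3H,0.78,0.011,fg
0,5,TPS2,0.27,0.006,fg
0,5,TPS1,1.02,0.014,i
0,5,OMT,0.8,0.013,hi
0,5,GDH1,2.14,0.05,fg
0,10,TPS27,0.39,0.004,f
0,10,L3H,0.77,0.008,fg
0,10,TPS2,0.08,0.001,i
0,10,TPS1,1.54,0.015,h
0,10,OMT,0.1,0.001,i
0,10,GDH1,6.53,0.09,e
0,15,TPS27,3.5,0.053,e
0,15,L3H,2.38,0.025,e
0,15,TPS2,0.2,0.003,h
0,15,TPS1,2.67,0.034,g
0,15,OMT,0.36,0.004,i
0,15,GDH1,6.25,0.13,e
0,20,TPS27,2.27,0.069,ef
0,20,L3H,1.88,0.034,e
0,20,TPS2,0.31,0.005,ef
0,20,TPS1,1.02,0.017,i
0,20,OMT,3.76,0.071,f
0,20,GDH1,1.78,0.03,gh
10,0,TPS27,6.4,0.085,d
10,0,L3H,4.81,0.049,d
10,0,TPS2,2.07,0.028,a
10,0,TPS1,3.63,0.038,f
10,0,OMT,6.45,0.064,e
10,0,GDH1,3.59,0.059,f
10,5,TPS27,4.16,0.089,de
10,5,L3H,2.11,0.041,e
10,5,TPS2,0.28,0.004,fg
10,5,TPS1,1.66,0.019,h
10,5,OMT,2.95,0.054,fg
10,5,GDH1,3.54,0.047,f
10,10,TPS27,30.39,0.583,b
10,10,L3H,18.22,0.344,a
10,10,TPS2,0.54,0.013,d
10,10,TPS1,10.98,0.203,c
10,10,OMT,8.13,0.168,d
10,10,GDH1,46.49,1.211,a
10,15,TPS27,94.39,1.73,a
10,15,L3H,13.38,0.203,b
10,15,TPS2,0.35,0.005,e
10,15,TPS1,11.63,0.12,b
10,15,OMT,5.48,0.116,e
10,15,GDH1,27.51,0.329,b
10,20,TPS27,21.48,0.427,c
10,20,L3H,10.64,0.209,c
10,20,TPS2,0.68,0.018,c
10,20,TPS1,3.56,0.067,f
10,20,OMT,34.88,0.707,b
10,20,GDH1,6.08,0.181,e
20,0,TPS27,0.1,0.002,f
20,0,L3H,0.01,0.001,h
20,0,TPS2,0.11,0.001,i
20,0,TPS1,0.42,0.005,j
20,0,OMT,2.24,0.034,fgh
20,0,GDH1,0.16,0.002,h
20,5,TPS27,0.1,0.003,f
20,5,L3H,0.01,0.002,h
20,5,TPS2,0.09,0.001,i
20,5,TPS1,1.76,0.017,h
20,5,OMT,2.27,0.036,fgh
20,5,GDH1,1.42,0.02,gh
20,10,TPS27,0.42,0.006,f
20,10,L3H,0.25,0.003,gh
20,10,TPS2,0.24,0.003,gh
20,10,TPS1,9.87,0.108,d
20,10,OMT,28.87,0.514,c
20,10,GDH1,15.94,0.202,c
20,15,TPS27,0.13,0.001,f
20,15,L3H,0.07,0.001,h
20,15,TPS2,0.11,0.003,i
20,15,TPS1,14.21,0.247,a
20,15,OMT,1.92,0.021,gh
20,15,GDH1,12.57,0.354,d
20,20,TPS27,0.15,0.003,f
20,20,L3H,0.17,0.002,h
20,20,TPS2,0.53,0.006,d
20,20,TPS1,8.5,0.083,e
20,20,OMT,62.68,0.797,a
20,20,GDH1,5.56,0.073,e
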