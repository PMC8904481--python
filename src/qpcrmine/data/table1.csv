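peg,proline,feature,mean,se,letters
0,0,SOD,2,0.095,h
0,0,PRO,0.25,0.005,h
0,0,H2O2,8.97,0.209,ij
0,0,SFW,16.3,0.38,c
0,0,RFW,1.6,0.032,de
0,5,SOD,2.6,0.026,f
0,5,PRO,0.55,0.014,f
0,5,H2O2,8.18,0.228,ij
0,5,SFW,18.76,0.144,b
0,5,RFW,1.93,0.046,b
0,10,SOD,1.45,0.019,i
0,10,PRO,0.71,0.013,c
0,10,H2O2,8.2,0.137,ij
0,10,SFW,21.41,0.135,a
0,10,RFW,1.4,0.016,f
0,15,SOD,1.96,0.033,h
0,15,PRO,0.49,0.011,f
0,15,H2O2,7.92,0.136,j
0,15,SFW,18.32,0.438,b
0,15,RFW,1.47,0.039,ef
0,20,SOD,2.9,0.031,e
0,20,PRO,0.42,0.008,g
0,20,H2O2,9.21,0.37,hi
0,20,SFW,9.96,0.136,d
0,20,RFW,1.92,0.034,b
10,0,SOD,3.55,0.035,d
10,0,PRO,0.7,0.013,cd
10,0,H2O2,13.65,0.307,e
10,0,SFW,6.19,0.149,f
10,0,RFW,2.32,0.027,a
10,5,SOD,2.46,0.055,fg
10,5,PRO,0.41,0.014,g
10,5,H2O2,12.56,0.153,ef
10,5,SFW,5.81,0.5,f
10,5,RFW,2.3,0.025,a
10,10,SOD,2.35,0.027,fg
10,10,PRO,0.91,0.018,a
10,10,H2O2,11.43,0.191,fg
10,10,SFW,7.93,0.185,e
10,10,RFW,1.76,0.035,c
10,15,SOD,2.29,0.03,g
10,15,PRO,0.85,0.017,ab
10,15,H2O2,10.39,0.295,gh
10,15,SFW,10.47,0.103,d
10,15,RFW,1.68,0.028,cd
10,20,SOD,3.34,0.035,d
10,20,PRO,0.9,0.01,a
10,20,H2O2,19.7,0.132,b
10,20,SFW,6.99,0.427,ef
10,20,RFW,0.63,0.029,j
20,0,SOD,7.11,0.033,a
20,0,PRO,0.63,0.017,e
20,0,H2O2,22.23,0.173,a
20,0,SFW,5.79,0.244,f
20,0,RFW,0.8,0.046,i
20,5,SOD,6.31,0.04,b
20,5,PRO,0.63,0.017,de
20,5,H2O2,18.67,0.311,bcd
20,5,SFW,4.4,0.232,gh
20,5,RFW,1.33,0.02,fg
20,10,SOD,4.13,0.039,c
20,10,PRO,0.87,0.008,ab
20,10,H2O2,18.39,0.324,cd
20,10,SFW,6.4,0.119,f
20,10,RFW,1.24,0.038,g
20,15,SOD,2.98,0.045,e
20,15,PRO,0.83,0.018,b
20,15,H2O2,17.72,0.15,d
20,15,SFW,5.12,0.256,fg
20,15,RFW,1,0.013,h
20,20,SOD,6.44,0.086,b
20,20,PRO,0.63,0.013,e
20,20,H2O2,19.45,0.328,bc
20,20,SFW,3.25,0.076,h
20,20,RFW,0.71,0.014,ij
0,0,"1,8-cineole",0.12,0.002,h
0,0,carvone,0.13,0.002,i
0,0,alpha-pinene,0.09,0.002,g
0,0,thymol,0.08,0.001,h
0,0,estragole,0.7,0.016,ef
0,0,beta-citronellol,0.18,0.004,i
0,5,"1,8-cineole",0.59,0.02,f
0,5,carvone,0.43,0.025,h
0,5,alpha-pinene,0.09,0.002,g
0,5,thymol,1.09,0.033,g
0,5,estragole,0.39,0.018,g
0,5,beta-citronellol,0.17,0.02,i
0,10,"1,8-cineole",0.64,0.011,ef
0,10,carvone,2.63,0.024,b
0,10,alpha-pinene,0.09,0.004,g
0,10,thymol,3.02,0.016,d
0,10,estragole,0.24,0.067,h
0,10,beta-citronellol,0.3,0.013,i
0,15,"1,8-cineole",0.84,0.01,d
0,15,carvone,2.33,0.006,c
0,15,alpha-pinene,0.03,0.002,i
0,15,thymol,4.16,0.018,c
0,15,estragole,0,0.009,j
0,15,beta-citronellol,0.5,0.003,h
0,20,"1,8-cineole",0.11,0.002,h
0,20,carvone,0.09,0.02,ij
0,20,alpha-pinene,0.1,0.002,fg
0,20,thymol,0.78,0.054,g
0,20,estragole,0.01,0.021,j
0,20,beta-citronellol,0.3,0.032,i
10,0,"1,8-cineole",0.96,0.011,cd
10,0,carvone,1.87,0.009,d
10,0,alpha-pinene,0.11,0.004,ef
10,0,thymol,1.98,0.014,e
10,0,estragole,0.79,0.027,de
10,0,beta-citronellol,0.99,0.011,f
10,5,"1,8-cineole",1.21,0.007,b
10,5,carvone,1.46,0.035,e
10,5,alpha-pinene,0.09,0.002,g
10,5,thymol,3.21,0.05,d
10,5,estragole,0.9,0.006,cd
10,5,beta-citronellol,1.6,0.006,d
10,10,"1,8-cineole",1.15,0.019,bc
10,10,carvone,2.74,0.037,a
10,10,alpha-pinene,0.08,0.002,h
10,10,thymol,4.13,0.069,c
10,10,estragole,0.61,0.014,f
10,10,beta-citronellol,2.73,0.055,b
10,15,"1,8-cineole",3.25,0.018,a
10,15,carvone,1.52,0.008,e
10,15,alpha-pinene,0.12,0.003,e
10,15,thymol,9.22,0.055,a
10,15,estragole,0.44,0.023,g
10,15,beta-citronellol,4.17,0.029,a
10,20,"1,8-cineole",0.02,0.014,i
10,20,carvone,0,0.031,j
10,20,alpha-pinene,0.11,0.001,ef
10,20,thymol,7.1,0.069,b
10,20,estragole,0.06,0.002,ij
10,20,beta-citronellol,2,0.01,c
20,0,"1,8-cineole",0.69,0.054,e
20,0,carvone,1.8,0.02,d
20,0,alpha-pinene,0.18,0.002,b
20,0,thymol,0.96,0.154,g
20,0,estragole,2.85,0.01,a
20,0,beta-citronellol,0.67,0.083,g
20,5,"1,8-cineole",0.45,0.008,g
20,5,carvone,0.67,0.001,fg
20,5,alpha-pinene,0.19,0.003,a
20,5,thymol,0.83,0.028,g
20,5,estragole,1.16,0.003,b
20,5,beta-citronellol,0.57,0.033,gh
20,10,"1,8-cineole",1.07,0.002,c
20,10,carvone,0.57,0.001,g
20,10,alpha-pinene,0.16,0.002,c
20,10,thymol,3.29,0.013,d
20,10,estragole,0.97,0.002,c
20,10,beta-citronellol,1.43,0.006,e
20,15,"1,8-cineole",0.5,0.003,g
20,15,carvone,0.01,0.002,j
20,15,alpha-pinene,0.14,0.002,d
20,15,thymol,1.66,0.118,f
20,15,estragole,0.15,0.001,hi
20,15,beta-citronellol,1.67,0.04,d
20,20,"1,8-cineole",0.01,0.001,i
20,20,carvone,0.68,0.009,f
20,20,alpha-pinene,0.17,0.003,bc
20,20,thymol,0.8,0.013,g
20,20,estragole,0.67,0.016,f
20,20,beta-citronellol,0.83,0.017,f
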