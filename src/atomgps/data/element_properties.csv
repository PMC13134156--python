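z,symbol,atomic_weight,group,period,block,valence_electrons,covalent_radius_pm,vdw_radius_pm,en_pauling,en_allen,electron_affinity_ev,ionization_energy_ev,melting_point_k,boiling_point_k,density_g_cm3,atomic_volume_cm3_mol
1,H,1.008,1,1,s,1,31,120,2.20,2.300,0.754,13.598,14.01,20.28,0.0000899,14.1
2,He,4.0026,18,1,s,2,28,140,,4.160,,24.587,0.95,4.22,0.000179,31.8
3,Li,6.94,1,2,s,1,128,182,0.98,0.912,0.618,5.392,453.65,1615,0.534,13.0
4,Be,9.0122,2,2,s,2,96,153,1.57,1.576,,9.323,1560,2742,1.85,4.9
5,B,10.81,13,2,p,3,84,192,2.04,2.051,0.280,8.298,2349,4200,2.34,4.4
6,C,12.011,14,2,p,4,76,170,2.55,2.544,1.262,11.260,3800,4300,2.267,5.3
7,N,14.007,15,2,p,5,71,155,3.04,3.066,-0.07,14.534,63.15,77.36,0.001251,17.3
8,O,15.999,16,2,p,6,66,152,3.44,3.610,1.461,13.618,54.36,90.19,0.001429,14.0
9,F,18.998,17,2,p,7,57,147,3.98,4.193,3.401,17.423,53.48,85.03,0.001696,17.1
10,Ne,20.180,18,2,p,8,58,154,,4.787,,21.565,24.56,27.07,0.000900,16.8
11,Na,22.990,1,3,s,1,166,227,0.93,0.869,0.548,5.139,370.87,1156,0.971,23.7
12,Mg,24.305,2,3,s,2,141,173,1.31,1.293,,7.646,923,1363,1.738,14.0
13,Al,26.982,13,3,p,3,121,184,1.61,1.613,0.433,5.986,933.47,2792,2.70,10.0
14,Si,28.085,14,3,p,4,111,210,1.90,1.916,1.390,8.152,1687,3538,2.329,12.1
15,P,30.974,15,3,p,5,107,180,2.19,2.253,0.746,10.487,317.30,550,1.823,17.0
16,S,32.06,16,3,p,6,105,180,2.58,2.589,2.077,10.360,388.36,717.8,2.067,15.5
17,Cl,35.45,17,3,p,7,102,175,3.16,2.869,3.613,12.968,171.6,239.11,0.003214,22.7
18,Ar,39.948,18,3,p,8,106,188,,3.242,,15.760,83.80,87.30,0.001784,24.2
19,K,39.098,1,4,s,1,203,275,0.82,0.734,0.501,4.341,336.53,1032,0.862,45.3
20,Ca,40.078,2,4,s,2,176,231,1.00,1.034,0.025,6.113,1115,1757,1.54,26.2
21,Sc,44.956,3,4,d,3,170,211,1.36,1.190,0.188,6.561,1814,3109,2.985,15.0
22,Ti,47.867,4,4,d,4,160,215,1.54,1.380,0.079,6.828,1941,3560,4.506,10.6
23,V,50.942,5,4,d,5,153,207,1.63,1.530,0.525,6.746,2183,3680,6.0,8.3
24,Cr,51.996,6,4,d,6,139,206,1.66,1.650,0.666,6.767,2180,2944,7.15,7.2
25,Mn,54.938,7,4,d,7,139,205,1.55,1.750,,7.434,1519,2334,7.3,7.4
26,Fe,55.845,8,4,d,8,132,204,1.83,1.800,0.151,7.902,1811,3134,7.874,7.1
27,Co,58.933,9,4,d,9,126,200,1.88,1.840,0.662,7.881,1768,3200,8.86,6.7
28,Ni,58.693,10,4,d,10,124,197,1.91,1.880,1.156,7.640,1728,3186,8.912,6.6
29,Cu,63.546,11,4,d,11,132,196,1.90,1.850,1.235,7.726,1357.77,2835,8.96,7.1
30,Zn,65.38,12,4,d,12,122,201,1.65,1.588,,9.394,692.68,1180,7.134,9.2
31,Ga,69.723,13,4,p,3,122,187,1.81,1.756,0.430,5.999,302.91,2477,5.91,11.8
32,Ge,72.630,14,4,p,4,120,211,2.01,1.994,1.233,7.899,1211.4,3106,5.323,13.6
33,As,74.922,15,4,p,5,119,185,2.18,2.211,0.804,9.789,1090,887,5.776,13.1
34,Se,78.971,16,4,p,6,120,190,2.55,2.424,2.021,9.752,494,958,4.809,16.5
35,Br,79.904,17,4,p,7,120,185,2.96,2.685,3.364,11.814,265.8,332.0,3.122,23.5
36,Kr,83.798,18,4,p,8,116,202,3.00,2.966,,14.000,115.79,119.93,0.003733,32.2
37,Rb,85.468,1,5,s,1,220,303,0.82,0.706,0.486,4.177,312.46,961,1.532,55.9
38,Sr,87.62,2,5,s,2,195,249,0.95,0.963,0.048,5.695,1050,1655,2.64,33.7
39,Y,88.906,3,5,d,3,190,232,1.22,1.120,0.307,6.217,1799,3609,4.47,19.8
40,Zr,91.224,4,5,d,4,175,223,1.33,1.320,0.426,6.634,2128,4682,6.52,14.1
41,Nb,92.906,5,5,d,5,164,218,1.60,1.410,0.893,6.759,2750,5017,8.57,10.8
42,Mo,95.95,6,5,d,6,154,217,2.16,1.470,0.748,7.092,2896,4912,10.2,9.4
43,Tc,98.0,7,5,d,7,147,216,1.90,1.510,0.550,7.280,2430,4538,11.0,8.5
44,Ru,101.07,8,5,d,8,146,213,2.20,1.540,1.050,7.360,2607,4423,12.1,8.3
45,Rh,102.906,9,5,d,9,142,210,2.28,1.560,1.137,7.459,2237,3968,12.4,8.3
46,Pd,106.42,10,5,d,10,139,210,2.20,1.580,0.562,8.337,1828.05,3236,12.0,8.9
47,Ag,107.868,11,5,d,11,145,211,1.93,1.870,1.302,7.576,1234.93,2435,10.49,10.3
48,Cd,112.414,12,5,d,12,144,218,1.69,1.520,,8.994,594.22,1040,8.69,13.0
49,In,114.818,13,5,p,3,142,193,1.78,1.656,0.300,5.786,429.75,2345,7.31,15.7
50,Sn,118.710,14,5,p,4,139,217,1.96,1.824,1.112,7.344,505.08,2875,7.287,16.3
51,Sb,121.760,15,5,p,5,139,206,2.05,1.984,1.046,8.608,903.78,1860,6.685,18.2
52,Te,127.60,16,5,p,6,138,206,2.10,2.158,1.971,9.010,722.66,1261,6.232,20.5
53,I,126.904,17,5,p,7,139,198,2.66,2.359,3.059,10.451,386.85,457.4,4.93,25.7
54,Xe,131.293,18,5,p,8,140,216,2.60,2.582,,12.130,161.4,165.03,0.005887,42.9
55,Cs,132.905,1,6,s,1,244,343,0.79,0.659,0.472,3.894,301.59,944,1.873,70.0
56,Ba,137.327,2,6,s,2,215,268,0.89,0.881,0.145,5.212,1000,2170,3.594,38.2
57,La,138.905,3,6,d,3,207,243,1.10,,0.470,5.577,1193,3737,6.145,22.5
58,Ce,140.116,3,6,f,4,204,242,1.12,,0.500,5.539,1068,3716,6.77,21.0
59,Pr,140.908,3,6,f,5,203,240,1.13,,0.500,5.473,1208,3793,6.773,20.8
60,Nd,144.242,3,6,f,6,201,239,1.14,,0.500,5.525,1297,3347,7.007,20.6
61,Pm,145.0,3,6,f,7,199,238,1.13,,0.500,5.582,1315,3273,7.26,20.2
62,Sm,150.36,3,6,f,8,198,236,1.17,,0.500,5.644,1345,2067,7.52,19.9
63,Eu,151.964,3,6,f,9,198,235,1.20,,0.500,5.670,1099,1802,5.243,28.9
64,Gd,157.25,3,6,f,10,196,234,1.20,,0.500,6.150,1585,3546,7.895,19.9
65,Tb,158.925,3,6,f,11,194,233,1.20,,0.500,5.864,1629,3503,8.229,19.2
66,Dy,162.500,3,6,f,12,192,231,1.22,,0.500,5.939,1680,2840,8.55,19.0
67,Ho,164.930,3,6,f,13,192,230,1.23,,0.500,6.022,1734,2993,8.795,18.7
68,Er,167.259,3,6,f,14,189,229,1.24,,0.500,6.108,1802,3141,9.066,18.4
69,Tm,168.934,3,6,f,15,190,227,1.25,,1.029,6.184,1818,2223,9.321,18.1
70,Yb,173.045,3,6,f,16,187,226,1.10,,-0.020,6.254,1097,1469,6.965,24.8
71,Lu,174.967,3,6,d,3,187,224,1.27,,0.340,5.426,1925,3675,9.84,17.8
72,Hf,178.49,4,6,d,4,175,223,1.30,1.160,0.017,6.825,2506,4876,13.31,13.6
73,Ta,180.948,5,6,d,5,170,222,1.50,1.340,0.322,7.550,3290,5731,16.69,10.9
74,W,183.84,6,6,d,6,162,218,2.36,1.470,0.815,7.864,3695,5828,19.25,9.5
75,Re,186.207,7,6,d,7,151,216,1.90,1.600,0.150,7.834,3459,5869,21.02,8.9
76,Os,190.23,8,6,d,8,144,216,2.20,1.650,1.100,8.438,3306,5285,22.59,8.4
77,Ir,192.217,9,6,d,9,141,213,2.20,1.680,1.564,8.967,2719,4701,22.56,8.5
78,Pt,195.084,10,6,d,10,136,213,2.28,1.720,2.128,8.959,2041.4,4098,21.46,9.1
79,Au,196.967,11,6,d,11,136,214,2.54,1.920,2.309,9.226,1337.33,3129,19.282,10.2
80,Hg,200.592,12,6,d,12,132,223,2.00,1.760,,10.438,234.43,629.88,13.534,14.8
81,Tl,204.38,13,6,p,3,145,196,1.62,1.789,0.377,6.108,577,1746,11.85,17.2
82,Pb,207.2,14,6,p,4,146,202,2.33,1.854,0.356,7.417,600.61,2022,11.342,18.3
83,Bi,208.980,15,6,p,5,148,207,2.02,2.010,0.942,7.286,544.7,1837,9.807,21.3
84,Po,209.0,16,6,p,6,140,197,2.00,2.190,1.900,8.417,527,1235,9.32,22.4
85,At,210.0,17,6,p,7,150,202,2.20,2.390,2.800,9.318,575,610,7.0,30.0
86,Rn,222.0,18,6,p,8,150,220,,2.600,,10.748,202,211.3,0.00973,50.5
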