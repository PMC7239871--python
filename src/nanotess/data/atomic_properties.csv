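symbol,R_cal,R_cov,R_emp,M,T_bol,rho,E_ea,chi,dH_fus,dH_vap,IE_1,IE_2,T_mel,V_mol,Q,lambda,q
H,53,31,25,1.008,20.3,0.00009,72.8,2.20,0.117,0.904,1312,0,14.0,11.42,14.30,0.1805,1
Li,167,128,145,6.94,1560,0.534,59.6,0.98,3.00,147.1,520.2,7298,453.7,13.02,3.582,84.8,1
Be,112,96,105,9.012,2742,1.85,0,1.57,7.90,297,899.5,1757,1560,4.85,1.825,200,2
B,87,84,85,10.81,4200,2.34,26.7,2.04,50.2,480,800.6,2427,2349,4.39,1.026,27.4,3
C,67,76,70,12.011,4300,2.26,121.8,2.55,117,715,1086,2353,3823,5.29,0.71,140,4
N,56,71,65,14.007,77.4,0.00125,0,3.04,0.72,5.57,1402,2856,63.1,13.54,1.04,0.02583,3
O,48,66,60,15.999,90.2,0.00143,141,3.44,0.444,6.82,1314,3388,54.4,17.36,0.92,0.02658,2
F,42,57,50,18.998,85.0,0.0017,328,3.98,0.51,6.62,1681,3374,53.5,11.20,0.824,0.0277,1
Na,190,166,180,22.990,1156,0.971,52.8,0.93,2.60,97.42,495.8,4562,370.9,23.78,1.228,142,1
Mg,145,141,150,24.305,1363,1.738,0,1.31,8.48,128,737.7,1451,923,14.00,1.023,156,2
Al,118,121,125,26.982,2792,2.70,42.5,1.61,10.71,294,577.5,1817,933.5,10.00,0.897,237,3
Si,111,111,110,28.085,3538,2.33,134,1.90,50.21,359,786.5,1577,1687,12.06,0.705,149,4
P,98,107,100,30.974,553.7,1.82,72,2.19,0.66,51.9,1012,1907,317.3,17.02,0.769,0.236,5
S,88,105,100,32.06,717.8,2.07,200,2.58,1.72,45,1000,2252,388.4,15.53,0.71,0.205,2
Cl,79,102,100,35.45,239.1,0.0032,349,3.16,6.41,20.4,1251,2298,171.6,17.39,0.479,0.0089,1
K,243,203,220,39.098,1032,0.862,48.4,0.82,2.33,76.9,418.8,3052,336.5,45.94,0.757,102.5,1
Ca,194,176,180,40.078,1757,1.54,2.37,1.00,8.54,154.7,589.8,1145,1115,26.20,0.647,201,2
Ti,176,160,140,47.867,3560,4.506,7.6,1.54,14.15,425,658.8,1310,1941,10.64,0.523,21.9,4
V,171,153,135,50.942,3680,6.0,50.6,1.63,21.5,459,650.9,1414,2183,8.32,0.489,30.7,5
Cr,166,139,140,51.996,2944,7.15,64.3,1.66,21.0,339.5,652.9,1591,2180,7.23,0.449,93.9,3
Mn,161,139,140,54.938,2334,7.3,0,1.55,12.91,221,717.3,1509,1519,7.35,0.479,7.81,2
Fe,156,132,140,55.845,3134,7.87,15.7,1.83,13.81,340,762.5,1562,1811,7.09,0.449,80.4,3
Co,152,126,135,58.933,3200,8.86,63.7,1.88,16.06,377,760.4,1648,1768,6.67,0.421,100,2
Ni,149,124,135,58.693,3186,8.90,112,1.91,17.48,379,737.1,1753,1728,6.59,0.444,90.9,2
Cu,145,132,135,63.546,2835,8.96,118.4,1.90,13.26,300.4,745.5,1958,1358,7.11,0.385,401,2
Zn,142,122,135,65.38,1180,7.134,0,1.65,7.32,123.6,906.4,1733,692.7,9.16,0.388,116,2
Ga,136,122,130,69.723,2673,5.91,28.9,1.81,5.59,254,578.8,1979,302.9,11.80,0.371,40.6,3
Ge,125,120,125,72.630,3106,5.323,119,2.01,36.94,334,762,1537,1211,13.63,0.320,60.2,4
As,114,119,115,74.922,887,5.776,78,2.18,24.44,32.4,947,1798,1090,12.95,0.329,50.2,3
Se,103,120,115,78.971,958,4.81,195,2.55,6.69,95.48,941,2045,494,16.42,0.321,0.52,2
Br,94,120,115,79.904,332,3.12,324.6,2.96,10.57,29.96,1140,2100,265.8,19.78,0.474,0.122,1
Sr,219,195,200,87.62,1655,2.64,5.03,0.95,7.43,141,549.5,1064,1050,33.94,0.301,35.4,2
Zr,206,175,155,91.224,4682,6.52,41.1,1.33,14.0,573,640.1,1270,2128,14.02,0.278,22.6,4
Mo,190,154,145,95.95,4912,10.2,71.9,2.16,37.48,617,684.3,1560,2896,9.38,0.251,138,6
Ru,178,146,130,101.07,4423,12.1,101.3,2.20,38.59,619,710.2,1620,2607,8.17,0.238,117,4
Rh,173,142,135,102.906,3968,12.4,109.7,2.28,26.59,494,719.7,1740,2237,8.28,0.243,150,3
Pd,169,139,140,106.42,3236,12.0,53.7,2.20,16.74,362,804.4,1870,1828,8.56,0.244,71.8,2
Ag,165,145,160,107.868,2435,10.5,125.6,1.93,11.28,254,731.0,2070,1235,10.27,0.235,429,1
Cd,161,144,155,112.414,1040,8.69,0,1.69,6.21,99.87,867.8,1631,594.2,13.00,0.232,96.6,2
In,156,142,155,114.818,2345,7.31,28.9,1.78,3.29,231.8,558.3,1821,429.7,15.76,0.233,81.8,3
Sn,145,139,145,118.710,2875,7.287,107.3,1.96,7.03,296.1,708.6,1412,505.1,16.29,0.228,66.8,4
Sb,133,139,145,121.760,1860,6.685,103.2,2.05,19.79,193.4,834,1595,903.8,18.19,0.207,24.4,3
Te,123,138,140,127.60,1261,6.232,190.2,2.10,17.49,114.1,869.3,1790,722.7,20.46,0.202,3.0,2
I,115,139,140,126.904,457.4,4.93,295.2,2.66,15.52,41.57,1008,1846,386.9,25.72,0.214,0.449,1
Cs,298,244,260,132.905,944,1.873,45.5,0.79,2.09,63.9,375.7,2234,301.6,70.94,0.242,35.9,1
Ba,253,215,215,137.327,2170,3.594,13.95,0.89,7.12,140.3,502.9,965.2,1000,38.16,0.204,18.4,2
La,226,207,195,138.905,3737,6.145,48,1.10,6.20,402.1,538.1,1067,1193,22.39,0.195,13.4,3
Ce,210,204,185,140.116,3716,6.77,50,1.12,5.46,398,534.4,1050,1068,20.69,0.192,11.3,4
W,193,162,135,183.84,5828,19.25,78.6,2.36,52.31,806.7,770,1700,3695,9.47,0.132,173,6
Os,185,144,130,190.23,5285,22.59,106.1,2.20,57.85,738,840,1600,3306,8.42,0.130,87.6,4
Ir,180,141,135,192.217,4701,22.56,151,2.20,41.12,564,880,1600,2719,8.52,0.131,147,4
Pt,177,136,135,195.084,4098,21.45,205.3,2.28,22.17,469,870,1791,2041,9.09,0.133,71.6,2
Au,174,136,135,196.967,3129,19.3,222.8,2.54,12.55,324,890.1,1980,1337,10.21,0.129,318,1
Hg,171,132,150,200.592,629.9,13.534,0,2.00,2.29,59.11,1007,1810,234.3,14.82,0.140,8.3,2
Tl,156,145,190,204.38,1746,11.85,19.2,1.62,4.14,165,589.4,1971,577,17.22,0.129,46.1,3
Pb,154,146,180,207.2,2022,11.34,35.1,2.33,4.77,179.5,715.6,1450,600.6,18.26,0.129,35.3,2
Bi,143,148,160,208.980,1837,9.78,91.2,2.02,11.30,151,703,1610,544.7,21.31,0.122,7.97,3
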