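variant,kf_s1,kf_err,ku_s1,ku_err,kpart,kpart_err,ddG_TS1N,ddG_TS1N_err,ddG_TS2N,ddG_TS2N_err,ddG_eq,ddG_eq_err,phi_ts1,phi_ts1_err,phi_ts2,phi_ts2_err
wt,300,13,0.06,0.01,0.017,0.003,,,,,,,,,,
L102A,280,12,0.05,0.01,0.013,0.003,-0.13,0.02,0.02,0.01,-0.10,0.06,,,,
A105G,330,14,0.07,0.02,0.036,0.008,0.06,0.02,-0.38,0.07,0.01,0.06,,,,
T108S,200,9,0.07,0.02,0.022,0.004,0.11,0.02,-0.05,0.01,0.36,0.06,,,,
L117A,90,6,0.96,0.14,0.037,0.006,1.65,0.15,1.20,0.20,2.40,0.40,0.31,0.13,0.50,0.12
A122G,110,4,0.04,0.01,0.018,0.003,-0.16,0.02,-0.21,0.04,0.42,0.08,1.38,0.07,1.51,0.09
L125A,100,5,0.17,0.03,0.018,0.002,0.61,0.03,0.60,0.10,1.20,0.20,0.50,0.03,0.53,0.13
L126A,280,13,0.34,0.06,0.031,0.006,1.03,0.06,0.70,0.10,1.10,0.20,0.04,0.08,0.37,0.08
T127S,260,13,0.06,0.01,0.017,0.003,0.01,0.02,0.01,0.02,0.10,0.02,,,,
L136A,90,7,0.68,0.10,0.045,0.008,1.45,0.11,0.90,0.20,2.10,0.40,0.32,0.05,0.60,0.08
V137A,20,1,0.003,0.001,0.012,0.002,-1.72,0.12,-1.50,0.30,-0.02,0.01,,,,
V148A,20,1,0.08,0.01,0.043,0.008,0.19,0.02,-0.36,0.07,1.70,0.30,0.89,0.05,1.21,0.04
L149A,28,2,0.06,0.01,0.028,0.005,-0.04,0.02,-0.34,0.07,1.40,0.30,1.00,0.10,1.25,0.05
T153S,260,13,0.01,0.01,0.070,0.030,-0.73,0.02,-1.50,0.30,-0.70,0.10,-0.13,0.17,-1.40,0.60
T168S,140,7,0.05,0.01,0.017,0.003,-0.12,0.02,-0.14,0.03,0.34,0.06,,,,
V170A,40,2,0.04,0.01,0.040,0.008,-0.21,0.02,-0.70,0.10,1.00,0.20,1.20,0.10,1.70,0.20
I172V,150,8,0.010,0.002,0.025,0.007,-1.05,0.10,-1.30,0.30,-0.70,0.10,-0.60,0.05,-0.95,0.40
L177A,330,16,0.007,0.002,0.022,0.007,-1.23,0.11,-1.40,0.30,-1.30,0.30,0.04,0.06,-0.08,0.22
V181A,170,8,0.08,0.02,0.027,0.005,0.16,0.01,-0.10,0.02,0.50,0.10,0.67,0.05,1.22,0.05
L190A,36,3,0.80,0.40,0.380,0.220,1.54,0.40,-0.30,0.06,2.80,0.40,0.45,0.13,1.11,0.10
T191S,260,13,0.06,0.01,0.021,0.004,-0.03,0.01,-0.17,0.03,0.05,0.02,,,,
L193A,120,8,0.28,0.05,0.060,0.010,0.93,0.05,0.24,0.05,1.50,0.40,0.37,0.04,0.84,0.03
V194A,38,4,1.80,0.30,0.150,0.040,2.00,0.40,0.70,0.20,3.30,0.80,0.38,0.10,0.77,0.04
V203A,190,8,0.15,0.03,0.026,0.004,0.55,0.03,0.30,0.06,0.80,0.10,0.33,0.06,0.63,0.08
T205S,230,11,0.05,0.01,0.023,0.005,-0.14,0.02,-0.33,0.06,0.00,0.01,,,,
L206A,210,10,0.04,0.01,0.022,0.004,-0.21,0.02,-0.36,0.07,0.00,0.01,,,,
T208S,270,15,0.11,0.02,0.040,0.010,0.38,0.03,-0.17,0.03,0.44,0.02,0.13,0.14,1.39,0.10
V209A,240,12,0.18,0.03,0.050,0.010,0.65,0.04,0.05,0.01,0.78,0.04,0.17,0.08,0.93,0.01
L210A,190,10,0.06,0.02,0.050,0.010,0.05,0.02,-0.60,0.10,0.31,0.02,,,,
L216A,460,23,0.67,0.12,0.024,0.004,1.44,0.13,1.20,0.30,1.20,0.10,-0.21,0.12,-0.03,0.21
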