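location,variant,n,ar,par,ho,he,fis
PT_VC,hIN,14,4.45,0.19,0.586,0.659,0.148
PT_VC,hOUT,13,4.43,0.16,0.572,0.660,0.174
SP_SG2,hIN,54,4.29,0.11,0.532,0.671,0.217
SP_SG2,hOUT,49,4.32,0.10,0.524,0.672,0.229
SP_SG3,hIN,22,4.27,0.13,0.590,0.680,0.156
SP_SG3,hOUT,19,4.21,0.10,0.576,0.665,0.162
SP_MU1,hIN,15,4.63,0.30,0.708,0.700,0.033
SP_MU1,hOUT,11,4.57,0.31,0.733,0.687,-0.01
SP_MU2,hIN,17,4.44,0.12,0.570,0.698,0.215
SP_MU2,hOUT,11,4.60,0.09,0.619,0.690,0.157
SP_SN2,hIN,19,4.45,0.11,0.570,0.687,0.197
SP_SN2,hOUT,12,4.42,0.13,0.624,0.662,0.101
SP_SN3,hIN,36,4.50,0.16,0.629,0.701,0.117
SP_SN3,hOUT,20,4.37,0.16,0.611,0.683,0.131
SP+PT,hIN,177,4.46,0.39,0.587,0.701,0.166
SP+PT,hOUT,135,4.43,0.40,0.584,0.696,0.165
REF_BL,hIN,11,4.48,0.13,0.717,0.661,-0.036
REF_BL,hOUT,11,4.48,0.18,0.717,0.661,-0.036
REF_FR,hIN,17,4.70,0.23,0.739,0.716,-0.001
REF_FR,hOUT,14,4.62,0.15,0.778,0.707,-0.064
PN_EY,hIN,15,4.16,0.11,0.588,0.630,0.107
PN_EY,hOUT,8,3.85,0.13,0.644,0.589,0.07
REF_SP80,hIN,34,4.69,0.36,0.498,0.710,0.314
REF_SP80,hOUT,33,4.66,0.37,0.488,0.706,0.326
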