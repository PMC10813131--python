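name,x,y,z
FP1,-0.02944,0.08392,-0.00699
FPZ,0.00011,0.08825,-0.00171
FP2,0.02987,0.08490,-0.00708
AF7,-0.05484,0.06857,-0.01059
AF3,-0.03370,0.07684,0.02123
AF4,0.03571,0.07773,0.02196
AF8,0.05574,0.06966,-0.01076
F7,-0.07026,0.04247,-0.01142
F5,-0.06447,0.04804,0.01692
F3,-0.05024,0.05311,0.04219
F1,-0.02750,0.05693,0.06034
FZ,0.00031,0.05851,0.06646
F2,0.02951,0.05760,0.05954
F4,0.05184,0.05430,0.04081
F6,0.06791,0.04983,0.01637
F8,0.07304,0.04442,-0.01200
FT7,-0.08077,0.01412,-0.01113
FC5,-0.07721,0.01864,0.02446
FC3,-0.06018,0.02272,0.05554
FC1,-0.03406,0.02601,0.07999
FCZ,0.00038,0.02739,0.08867
FC2,0.03478,0.02644,0.07881
FC4,0.06229,0.02372,0.05563
FC6,0.07953,0.01994,0.02444
FT8,0.08182,0.01542,-0.01133
T7,-0.08416,-0.01602,-0.00935
C5,-0.08028,-0.01376,0.02916
C3,-0.06536,-0.01163,0.06436
C1,-0.03616,-0.00998,0.08975
CZ,0.00040,-0.00917,0.10024
C2,0.03767,-0.00962,0.08841
C4,0.06712,-0.01090,0.06358
C6,0.08346,-0.01278,0.02921
T8,0.08508,-0.01502,-0.00949
TP7,-0.08483,-0.04602,-0.00706
CP5,-0.07959,-0.04655,0.03095
CP3,-0.06356,-0.04701,0.06562
CP1,-0.03551,-0.04729,0.09131
CPZ,0.00039,-0.04732,0.09943
CP2,0.03838,-0.04707,0.09069
CP4,0.06661,-0.04664,0.06558
CP6,0.08332,-0.04610,0.03121
TP8,0.08555,-0.04555,-0.00713
P7,-0.07243,-0.07345,-0.00249
P5,-0.06727,-0.07629,0.02838
P3,-0.05301,-0.07879,0.05594
P1,-0.02862,-0.08052,0.07544
PZ,0.00032,-0.08111,0.08261
P2,0.03192,-0.08049,0.07672
P4,0.05567,-0.07856,0.05656
P6,0.06789,-0.07590,0.02809
P8,0.07306,-0.07307,-0.00254
PO7,-0.05484,-0.09753,0.00279
PO5,-0.04842,-0.09934,0.02160
PO3,-0.03651,-0.10085,0.03717
POZ,0.00022,-0.10218,0.05061
PO4,0.03678,-0.10085,0.03640
PO6,0.04982,-0.09945,0.02173
PO8,0.05567,-0.09763,0.00273
O1,-0.02941,-0.11245,0.00884
OZ,0.00011,-0.11489,0.01466
O2,0.02984,-0.11216,0.00880
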