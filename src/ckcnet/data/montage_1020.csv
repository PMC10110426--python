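label,x,y,z
Fp1,-0.285188,0.958132,-0.025512
Fp2,0.274900,0.961116,-0.026193
F7,-0.762866,0.642002,-0.076609
F3,-0.516933,0.714108,0.472048
Fz,-0.003412,0.730672,0.682721
F4,0.517724,0.723632,0.456419
F8,0.758840,0.646250,-0.080760
M1,-0.780485,-0.249893,-0.573059
T3,-0.998134,0.014099,-0.059408
C3,-0.691971,0.058537,0.719548
Cz,-0.002527,0.076775,0.997045
C4,0.698024,0.066351,0.712993
T4,0.997777,0.025964,-0.061379
M2,0.774493,-0.252854,-0.579849
T5,-0.792446,-0.609627,0.019623
P3,-0.528849,-0.606667,0.593526
Pz,-0.003162,-0.592340,0.805682
P4,0.536963,-0.598883,0.594147
T6,0.791595,-0.610744,0.019215
O1,-0.298613,-0.945422,0.130410
O2,0.291241,-0.947675,0.130735
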