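label,hemisphere,lobe
F1-lh,left,F
F1-rh,right,F
F2-lh,left,F
F2-rh,right,F
F3-lh,left,F
F3-rh,right,F
F4-lh,left,F
F4-rh,right,F
F5-lh,left,F
F5-rh,right,F
F6-lh,left,F
F6-rh,right,F
F7-lh,left,F
F7-rh,right,F
F8-lh,left,F
F8-rh,right,F
F9-lh,left,F
F9-rh,right,F
C1-lh,left,C
C1-rh,right,C
C2-lh,left,C
C2-rh,right,C
C3-lh,left,C
C3-rh,right,C
C4-lh,left,C
C4-rh,right,C
C5-lh,left,C
C5-rh,right,C
C6-lh,left,C
C6-rh,right,C
C7-lh,left,C
C7-rh,right,C
C8-lh,left,C
C8-rh,right,C
T1-lh,left,T
T1-rh,right,T
T2-lh,left,T
T2-rh,right,T
T3-lh,left,T
T3-rh,right,T
T4-lh,left,T
T4-rh,right,T
T5-lh,left,T
T5-rh,right,T
T6-lh,left,T
T6-rh,right,T
O1-lh,left,O
O1-rh,right,O
O2-lh,left,O
O2-rh,right,O
O3-lh,left,O
O3-rh,right,O
O4-lh,left,O
O4-rh,right,O
O5-lh,left,O
O5-rh,right,O
O6-lh,left,O
O6-rh,right,O
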