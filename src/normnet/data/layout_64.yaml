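channels:
- FP1
- FPZ
- FP2
- AF3
- AF4
- F7
- F5
- F3
- F1
- FZ
- F2
- F4
- F6
- F8
- FT7
- FC5
- FC3
- FC1
- FCZ
- FC2
- FC4
- FC6
- FT8
- T7
- C5
- C3
- C1
- CZ
- C2
- C4
- C6
- T8
- M1
- TP7
- CP5
- CP3
- CP1
- CPZ
- CP2
- CP4
- CP6
- TP8
- M2
- P7
- P5
- P3
- P1
- PZ
- P2
- P4
- P6
- P8
- PO7
- PO5
- PO3
- POZ
- PO4
- PO6
- PO8
- CB1
- O1
- OZ
- O2
- CB2
positions:
  FP1:
  - -1.0
  - 4.0
  FPZ:
  - 0.0
  - 4.0
  FP2:
  - 1.0
  - 4.0
  AF3:
  - -2.0
  - 3.0
  AF4:
  - 2.0
  - 3.0
  F7:
  - -4.0
  - 2.0
  F5:
  - -3.0
  - 2.0
  F3:
  - -2.0
  - 2.0
  F1:
  - -1.0
  - 2.0
  FZ:
  - 0.0
  - 2.0
  F2:
  - 1.0
  - 2.0
  F4:
  - 2.0
  - 2.0
  F6:
  - 3.0
  - 2.0
  F8:
  - 4.0
  - 2.0
  FT7:
  - -4.0
  - 1.0
  FC5:
  - -3.0
  - 1.0
  FC3:
  - -2.0
  - 1.0
  FC1:
  - -1.0
  - 1.0
  FCZ:
  - 0.0
  - 1.0
  FC2:
  - 1.0
  - 1.0
  FC4:
  - 2.0
  - 1.0
  FC6:
  - 3.0
  - 1.0
  FT8:
  - 4.0
  - 1.0
  T7:
  - -4.0
  - 0.0
  C5:
  - -3.0
  - 0.0
  C3:
  - -2.0
  - 0.0
  C1:
  - -1.0
  - 0.0
  CZ:
  - 0.0
  - 0.0
  C2:
  - 1.0
  - 0.0
  C4:
  - 2.0
  - 0.0
  C6:
  - 3.0
  - 0.0
  T8:
  - 4.0
  - 0.0
  M1:
  - -5.0
  - -0.8
  TP7:
  - -4.0
  - -1.0
  CP5:
  - -3.0
  - -1.0
  CP3:
  - -2.0
  - -1.0
  CP1:
  - -1.0
  - -1.0
  CPZ:
  - 0.0
  - -1.0
  CP2:
  - 1.0
  - -1.0
  CP4:
  - 2.0
  - -1.0
  CP6:
  - 3.0
  - -1.0
  TP8:
  - 4.0
  - -1.0
  M2:
  - 5.0
  - -0.8
  P7:
  - -4.0
  - -2.0
  P5:
  - -3.0
  - -2.0
  P3:
  - -2.0
  - -2.0
  P1:
  - -1.0
  - -2.0
  PZ:
  - 0.0
  - -2.0
  P2:
  - 1.0
  - -2.0
  P4:
  - 2.0
  - -2.0
  P6:
  - 3.0
  - -2.0
  P8:
  - 4.0
  - -2.0
  PO7:
  - -4.0
  - -3.0
  PO5:
  - -3.0
  - -3.0
  PO3:
  - -2.0
  - -3.0
  POZ:
  - 0.0
  - -3.0
  PO4:
  - 2.0
  - -3.0
  PO6:
  - 3.0
  - -3.0
  PO8:
  - 4.0
  - -3.0
  CB1:
  - -2.0
  - -4.4
  O1:
  - -1.0
  - -4.0
  OZ:
  - 0.0
  - -4.0
  O2:
  - 1.0
  - -4.0
  CB2:
  - 2.0
  - -4.4
regions:
  left frontal:
  - F3
  - F5
  - F7
  - FC3
  - FC5
  - FT7
  left central:
  - C3
  - C5
  - CP3
  - CP5
  - TP7
  left parietal:
  - P3
  - P5
  - P7
  - PO5
  - PO7
  - O1
  medial frontal:
  - F1
  - FZ
  - F2
  - FC1
  - FCZ
  - FC2
  medial central:
  - C1
  - CZ
  - C2
  - CP1
  - CPZ
  - CP2
  medial parietal:
  - P1
  - PZ
  - P2
  - PO3
  - POZ
  - PO4
  right frontal:
  - F4
  - F6
  - F8
  - FC4
  - FC6
  - FT8
  right central:
  - C4
  - C6
  - CP4
  - CP6
  - TP8
  right parietal:
  - P4
  - P6
  - P8
  - PO6
  - PO8
  - O2
excluded:
- CB1
- CB2
- M1
- M2
neighbor_threshold: 1.45
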