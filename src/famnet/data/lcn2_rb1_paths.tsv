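no	path
1	LCN2 -> HGF -> FN1 -> RBBP4 -> RB1
2	LCN2 -> HGF -> FN1 -> SUMO2 -> RB1
3	LCN2 -> HGF -> FN1 -> HDAC1 -> RB1
4	LCN2 -> HGF -> FN1 -> UBC -> RB1
5	LCN2 -> LRP2 -> RBP1 -> SIRT1 -> RB1
6	LCN2 -> LRP2 -> RBP1 -> RBBP7 -> RB1
7	LCN2 -> LRP2 -> RBP1 -> HDAC2 -> RB1
8	LCN2 -> LRP2 -> APP -> MORF4L1 -> RB1
9	LCN2 -> LRP2 -> APP -> PPARG -> RB1
10	LCN2 -> LRP2 -> APP -> CCND3 -> RB1
11	LCN2 -> LRP2 -> RBP1 -> RBBP4 -> RB1
12	LCN2 -> LRP2 -> RBP1 -> HDAC1 -> RB1
13	LCN2 -> LRP2 -> APP -> UBC -> RB1
14	LCN2 -> LRP2 -> SERPINE1 -> UBC -> RB1
15	LCN2 -> LRP2 -> ALB -> UBC -> RB1
16	LCN2 -> LRP2 -> RBP1 -> UBC -> RB1
17	LCN2 -> MMP9 -> FN1 -> RBBP4 -> RB1
18	LCN2 -> MMP9 -> FN1 -> SUMO2 -> RB1
19	LCN2 -> MMP9 -> FN1 -> HDAC1 -> RB1
20	LCN2 -> MMP9 -> FN1 -> UBC -> RB1
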