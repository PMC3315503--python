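((LCL_1:0.0800,LCL_2:0.0800,LCL_3:0.0800):0.3500,(DCL_1:0.0800,DCL_2:0.0800,DCL_3:0.0800):0.3500,(Starter_1:0.0800,Starter_2:0.0800,Starter_3:0.0800):0.3500,(Cyclization_1:0.0800,Cyclization_2:0.0800,Cyclization_3:0.0800):0.3500,(Epimerization_1:0.0800,Epimerization_2:0.0800,Epimerization_3:0.0800):0.3500,(DualEC_1:0.0800,DualEC_2:0.0800,DualEC_3:0.0800):0.3500,(ModifiedAA_1:0.0800,ModifiedAA_2:0.0800,ModifiedAA_3:0.0800):0.3500,(HybridC_1:0.0800,HybridC_2:0.0800,HybridC_3:0.0800):0.3500);
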