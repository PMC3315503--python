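((Enediyne_1:0.0800,Enediyne_2:0.0800,Enediyne_3:0.0800):0.3500,(TransAT_1:0.0800,TransAT_2:0.0800,TransAT_3:0.0800):0.3500,(CisAT_1:0.0800,CisAT_2:0.0800,CisAT_3:0.0800):0.3500,(Hybrid_1:0.0800,Hybrid_2:0.0800,Hybrid_3:0.0800):0.3500,(Iterative_1:0.0800,Iterative_2:0.0800,Iterative_3:0.0800):0.3500,(PUFA_1:0.0800,PUFA_2:0.0800,PUFA_3:0.0800):0.3500,(KS1_1:0.0800,KS1_2:0.0800,KS1_3:0.0800):0.3500,(TypeII_1:0.0800,TypeII_2:0.0800,TypeII_3:0.0800):0.3500,(FAS_1:0.0800,FAS_2:0.0800,FAS_3:0.0800):0.3500);
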