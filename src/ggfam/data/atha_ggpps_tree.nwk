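(GGPPS12,((GGPPS2,GGPPS11),((GGPPS3,GGPPS4),((GGPPS1,GGPPS8),(GGPPS5,((GGPPS6,GGPPS7),(GGPPS9,GGPPS10)))))));
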