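tip_label	state
GGPPS1	7
GGPPS2	1
GGPPS3	3
GGPPS4	4
GGPPS5	5
GGPPS6	8
GGPPS7	8
GGPPS8	5
GGPPS9	6
GGPPS10	6
GGPPS11	2
GGPPS12	2
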