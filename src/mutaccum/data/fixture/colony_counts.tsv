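line_id	group	bottleneck	colony_cells
25C_line01	25C	1	136845201.85617456
25C_line01	25C	11	142898894.8800724
25C_line01	25C	21	125974664.12137948
25C_line02	25C	1	126183667.24160509
25C_line02	25C	11	128782890.86889207
25C_line02	25C	21	132260186.92822751
28C_line01	28C	1	153987034.67359582
28C_line01	28C	11	162047975.21539268
28C_line01	28C	21	116182289.53728986
28C_line02	28C	1	142079662.28132653
28C_line02	28C	11	122726167.552087
28C_line02	28C	21	140871153.52892464
37C_line01	37C	1	153026980.09849155
37C_line01	37C	11	116473888.35362133
37C_line01	37C	21	154330670.85537487
37C_line02	37C	1	121111760.96360788
37C_line02	37C	11	148862620.81716716
37C_line02	37C	21	123417869.0145562
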