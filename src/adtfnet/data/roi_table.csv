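condition,name,x_mm,y_mm,z_mm,radius_mm
LVF,rTPJ,45,-54,30,6
LVF,rSTG,63,-39,18,6
LVF,rA1,45,-21,12,10
LVF,rV1,9,96,-3,10
RVF,rTPJ,45,-54,33,6
RVF,lSTG,-64,-46,18,6
RVF,lA1,-40,-26,14,10
RVF,lV1,-9,-96,-9,10
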