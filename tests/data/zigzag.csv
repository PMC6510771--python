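time_s,x_cm,y_cm
0.0,-60.0,-20.0
0.2,-50.0,-20.0
0.4,-50.0,-10.0
0.6,-40.0,-10.0
0.8,-40.0,-20.0
1.0,-30.0,-20.0
1.2,-30.0,-10.0
1.4,-20.0,-10.0
1.6,-20.0,-20.0
1.8,-10.0,-20.0
2.0,-10.0,-10.0
2.2,0.0,-10.0
2.4,0.0,-20.0
2.6,10.0,-20.0
2.8,10.0,-10.0
3.0,20.0,-10.0
3.2,20.0,-20.0
3.4,30.0,-20.0
3.6,30.0,-10.0
3.8,40.0,-10.0
4.0,40.0,-20.0
4.2,50.0,-20.0
4.4,50.0,-10.0
4.6,60.0,-10.0
4.8,60.0,-20.0
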