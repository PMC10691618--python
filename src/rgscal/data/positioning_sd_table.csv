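point,mode,vertical_cm,longitudinal_cm,lateral_cm
#1,manual_with_laser,0.020,0.041,0.041
#1,couch_move,0.006,0.016,0.000
#3,manual,0.020,0.173,0.141
#3,couch_move,0.005,0.025,0.000
#7,manual,0.024,0.165,0.157
#7,couch_move,0.008,0.025,0.000
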