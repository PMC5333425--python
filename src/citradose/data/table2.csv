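session,ht_percent,pcai0,wbci,ccai_t5,ccai_max,ptf,tf
A.1,40,1.14,2.4,0.40,0.42,Y,N
B.1,27,1.00,2.4,0.37,0.37,Y,Y
B.2,25,1.07,2.4,0.41,0.41,Y,N
B.3,26,0.83,2.4,0.40,0.47,Y,Y
C.1,27,1.27,3.0,0.39,0.39,y,
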