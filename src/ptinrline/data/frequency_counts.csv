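phase,method_id,inr_lt_2,inr_2_to_3,inr_3_to_4,inr_4_to_5,inr_ge_5
before,coaguchek_xs,31,42,29,11,7
before,utmb_stago,42,58,17,3,0
before,arup_stago,38,55,21,6,0
before,bcs_xp,32,42,27,15,3
after,coaguchek_xs,31,42,29,11,7
after,utmb_stago,43,54,17,5,1
after,arup_stago,40,48,22,9,1
after,bcs_xp,39,37,24,8,11
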