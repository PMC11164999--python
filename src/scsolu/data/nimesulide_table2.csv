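T_K,P_bar,y2,u_y,y2_lit
312,160,3.22e-5,,3.18e-5
312,190,5.18e-5,,5.11e-5
312,220,7.53e-5,,7.42e-5
331,160,3.92e-5,,3.80e-5
331,190,7.19e-5,,7.08e-5
331,220,9.95e-5,,9.85e-5
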