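T_K,P_bar,rho_kg_m3
308.15,120,767.743797
308.15,160,827.243831
308.15,200,865.734983
308.15,240,894.879210
308.15,280,918.636413
308.15,320,938.843200
308.15,360,956.510802
308.15,400,972.260531
318.15,120,658.804737
318.15,160,760.077361
318.15,200,812.699053
318.15,240,849.396844
318.15,280,878.001063
318.15,320,901.652724
318.15,360,921.932491
318.15,400,939.752769
328.15,120,504.391512
328.15,160,681.074181
328.15,200,754.576045
328.15,240,801.163787
328.15,280,835.701367
328.15,320,863.392840
328.15,360,886.646237
328.15,400,906.773061
338.15,120,382.814010
338.15,160,592.404876
338.15,200,691.601522
338.15,240,750.359917
338.15,280,791.915614
338.15,320,824.226323
338.15,360,850.795179
338.15,400,873.445873
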