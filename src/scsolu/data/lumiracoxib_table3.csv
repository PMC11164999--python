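T_K,P_bar,y2,u_y
308.15,120,8.81e-5,7.16e-6
308.15,160,1.23e-4,9.17e-6
308.15,200,1.45e-4,4.25e-6
308.15,240,1.76e-4,7.77e-6
308.15,280,1.99e-4,8.17e-6
308.15,320,2.23e-4,1.45e-6
308.15,360,2.68e-4,8.47e-6
308.15,400,2.91e-4,2.06e-5
318.15,120,6.66e-5,4.83e-6
318.15,160,1.11e-4,3.86e-6
318.15,200,1.68e-4,4.52e-6
318.15,240,2.01e-4,1.19e-5
318.15,280,2.19e-4,3.12e-5
318.15,320,2.44e-4,1.11e-5
318.15,360,2.84e-4,1.06e-5
318.15,400,3.06e-4,1.43e-5
328.15,120,4.74e-5,3.59e-6
328.15,160,9.97e-5,4.61e-6
328.15,200,1.88e-4,1.29e-5
328.15,240,2.15e-4,1.33e-5
328.15,280,2.42e-4,8.67e-6
328.15,320,2.71e-4,1.13e-5
328.15,360,3.01e-4,7.78e-6
328.15,400,3.19e-4,2.18e-5
338.15,160,7.49e-5,3.64e-6
338.15,200,2.09e-4,1.67e-5
338.15,240,2.33e-4,1.98e-5
338.15,280,2.68e-4,1.89e-5
338.15,320,2.93e-4,2.09e-5
338.15,360,3.28e-4,2.49e-5
338.15,400,3.46e-4,9.24e-6
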