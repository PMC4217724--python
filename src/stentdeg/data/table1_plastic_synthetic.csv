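# Synthetic companion plastic curves for the tensile grid fixture.
# The published stress-strain curves are graphical only; these are the nominal
# pristine PLLA hardening curve scaled down monotonically with each cell's
# degradation degree (synthetic, not measured data).
pre_stretch,time_days,plastic_strain,true_stress_MPa
0.0,3.0,0.0,54.9
0.0,3.0,0.02,71.37
0.0,3.0,0.05,84.18
0.0,3.0,0.1,96.075
0.0,3.0,0.2,111.63
0.0,3.0,0.4,132.675
0.0,3.0,0.7,146.4
0.0,3.0,1.0,155.55
0.0,3.0,1.4,161.04
0.0,10.0,0.0,52.682
0.0,10.0,0.02,68.4866
0.0,10.0,0.05,80.779
0.0,10.0,0.1,92.1935
0.0,10.0,0.2,107.12
0.0,10.0,0.4,127.3148
0.0,10.0,0.7,140.4853
0.0,10.0,1.0,149.2656
0.0,10.0,1.4,154.5338
0.0,20.0,0.0,52.8469
0.0,20.0,0.02,68.701
0.0,20.0,0.05,81.0319
0.0,20.0,0.1,92.4821
0.0,20.0,0.2,107.4554
0.0,20.0,0.4,127.7134
0.0,20.0,0.7,140.9251
0.0,20.0,1.0,149.7329
0.0,20.0,1.4,155.0176
0.0,30.0,0.0,50.3283
0.0,30.0,0.02,65.4268
0.0,30.0,0.05,77.17
0.0,30.0,0.1,88.0745
0.0,30.0,0.2,102.3342
0.0,30.0,0.4,121.6267
0.0,30.0,0.7,134.2088
0.0,30.0,1.0,142.5968
0.0,30.0,1.4,147.6296
0.2,3.0,0.0,50.8185
0.2,3.0,0.02,66.064
0.2,3.0,0.05,77.9216
0.2,3.0,0.1,88.9323
0.2,3.0,0.2,103.3308
0.2,3.0,0.4,122.8113
0.2,3.0,0.7,135.5159
0.2,3.0,1.0,143.9856
0.2,3.0,1.4,149.0675
0.2,10.0,0.0,32.1827
0.2,10.0,0.02,41.8376
0.2,10.0,0.05,49.3469
0.2,10.0,0.1,56.3198
0.2,10.0,0.2,65.4382
0.2,10.0,0.4,77.775
0.2,10.0,0.7,85.8206
0.2,10.0,1.0,91.1844
0.2,10.0,1.4,94.4027
0.2,20.0,0.0,29.4806
0.2,20.0,0.02,38.3247
0.2,20.0,0.05,45.2035
0.2,20.0,0.1,51.591
0.2,20.0,0.2,59.9438
0.2,20.0,0.4,71.2447
0.2,20.0,0.7,78.6148
0.2,20.0,1.0,83.5283
0.2,20.0,1.4,86.4763
0.2,30.0,0.0,22.4315
0.2,30.0,0.02,29.1609
0.2,30.0,0.05,34.3949
0.2,30.0,0.1,39.255
0.2,30.0,0.2,45.6106
0.2,30.0,0.4,54.2093
0.2,30.0,0.7,59.8172
0.2,30.0,1.0,63.5558
0.2,30.0,1.4,65.7989
0.4,3.0,0.0,35.4425
0.4,3.0,0.02,46.0752
0.4,3.0,0.05,54.3451
0.4,3.0,0.1,62.0243
0.4,3.0,0.2,72.0664
0.4,3.0,0.4,85.6526
0.4,3.0,0.7,94.5133
0.4,3.0,1.0,100.4203
0.4,3.0,1.4,103.9646
0.4,10.0,0.0,34.8811
0.4,10.0,0.02,45.3454
0.4,10.0,0.05,53.4843
0.4,10.0,0.1,61.0419
0.4,10.0,0.2,70.9249
0.4,10.0,0.4,84.2959
0.4,10.0,0.7,93.0162
0.4,10.0,1.0,98.8297
0.4,10.0,1.4,102.3178
0.4,20.0,0.0,24.2143
0.4,20.0,0.02,31.4785
0.4,20.0,0.05,37.1285
0.4,20.0,0.1,42.375
0.4,20.0,0.2,49.2357
0.4,20.0,0.4,58.5178
0.4,20.0,0.7,64.5714
0.4,20.0,1.0,68.6071
0.4,20.0,1.4,71.0285
0.4,30.0,0.0,20.3966
0.4,30.0,0.02,26.5156
0.4,30.0,0.05,31.2749
0.4,30.0,0.1,35.6941
0.4,30.0,0.2,41.4732
0.4,30.0,0.4,49.2919
0.4,30.0,0.7,54.3911
0.4,30.0,1.0,57.7905
0.4,30.0,1.4,59.8302
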