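sex,tooth,stage,score_years
M,31,C,6.141
M,31,D,4.656
M,31,E,5.847
M,31,F,5.383
M,31,G,5.874
M,31,H,5.556
M,32,C,0.000
M,32,D,0.000
M,32,E,-0.702
M,32,F,-0.226
M,32,G,0.083
M,32,H,0.562
M,33,C,0.000
M,33,D,0.213
M,33,E,0.633
M,33,F,1.244
M,33,G,1.518
M,33,H,1.763
M,34,B,0.011
M,34,C,1.189
M,34,D,1.162
M,34,E,0.638
M,34,F,0.974
M,34,G,2.475
M,34,H,2.707
M,35,B,-0.293
M,35,C,-0.390
M,35,D,-0.456
M,35,E,0.214
M,35,F,0.399
M,35,G,0.612
M,35,H,2.147
M,36,B,0.000
M,36,D,-1.486
M,36,E,-1.252
M,36,F,-1.130
M,36,G,-0.413
M,36,H,-0.198
M,37,B,0.160
M,37,C,0.522
M,37,D,0.992
M,37,E,1.514
M,37,F,1.872
M,37,G,2.555
M,37,H,3.654
F,31,D,11.204
F,31,E,11.403
F,31,F,12.426
F,31,G,12.948
F,31,H,11.855
F,32,C,0.000
F,32,D,-0.084
F,32,E,0.000
F,32,F,-0.601
F,32,G,-0.349
F,32,H,0.165
F,33,B,0.000
F,33,C,-4.567
F,33,D,-5.126
F,33,E,-5.176
F,33,F,-4.347
F,33,G,-3.385
F,33,H,-3.024
F,34,B,0.000
F,34,C,0.000
F,34,D,0.279
F,34,E,0.308
F,34,F,0.412
F,34,G,0.886
F,34,H,1.976
F,35,B,-1.355
F,35,C,-0.376
F,35,D,-0.869
F,35,E,-0.513
F,35,F,-0.325
F,35,G,-0.103
F,35,H,1.999
F,36,B,0.000
F,36,D,0.000
F,36,E,-0.300
F,36,F,0.032
F,36,G,0.266
F,36,H,0.661
F,37,B,-0.095
F,37,C,-0.221
F,37,D,0.134
F,37,E,0.589
F,37,F,0.503
F,37,G,0.899
F,37,H,2.578
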