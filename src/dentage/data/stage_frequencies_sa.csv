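sex,tooth,stage,percent
F,31,A,0.00
F,31,B,0.00
F,31,C,0.00
F,31,D,2.88
F,31,E,9.76
F,31,F,12.32
F,31,G,31.04
F,31,H,44.00
F,32,A,0.00
F,32,B,0.00
F,32,C,0.16
F,32,D,2.72
F,32,E,12.32
F,32,F,17.12
F,32,G,25.12
F,32,H,42.56
F,33,A,0.00
F,33,B,0.16
F,33,C,0.48
F,33,D,6.88
F,33,E,25.12
F,33,F,28.00
F,33,G,13.12
F,33,H,26.24
F,34,A,0.00
F,34,B,0.16
F,34,C,4.00
F,34,D,8.16
F,34,E,31.20
F,34,F,21.28
F,34,G,9.60
F,34,H,25.60
F,35,A,0.80
F,35,B,1.44
F,35,C,3.36
F,35,D,8.96
F,35,E,33.12
F,35,F,21.44
F,35,G,6.72
F,35,H,24.16
F,36,A,0.00
F,36,B,0.16
F,36,C,0.00
F,36,D,1.76
F,36,E,11.68
F,36,F,6.72
F,36,G,37.12
F,36,H,42.56
F,37,A,0.80
F,37,B,0.80
F,37,C,2.08
F,37,D,22.08
F,37,E,28.48
F,37,F,14.24
F,37,G,12.48
F,37,H,19.04
M,31,A,0.00
M,31,B,0.00
M,31,C,0.14
M,31,D,2.23
M,31,E,11.87
M,31,F,10.75
M,31,G,30.17
M,31,H,44.83
M,32,A,0.00
M,32,B,0.00
M,32,C,0.14
M,32,D,2.51
M,32,E,14.25
M,32,F,15.36
M,32,G,25.14
M,32,H,42.60
M,33,A,0.00
M,33,B,0.00
M,33,C,0.42
M,33,D,6.56
M,33,E,29.05
M,33,F,27.79
M,33,G,9.22
M,33,H,26.96
M,34,A,0.14
M,34,B,0.28
M,34,C,3.77
M,34,D,9.22
M,34,E,33.52
M,34,F,18.58
M,34,G,7.40
M,34,H,27.09
M,35,A,0.70
M,35,B,1.82
M,35,C,4.47
M,35,D,8.94
M,35,E,32.96
M,35,F,18.30
M,35,G,7.82
M,35,H,25.00
M,36,A,0.00
M,36,B,0.42
M,36,C,0.00
M,36,D,1.96
M,36,E,12.15
M,36,F,6.42
M,36,G,34.36
M,36,H,44.69
M,37,A,1.40
M,37,B,1.54
M,37,C,2.51
M,37,D,23.18
M,37,E,28.49
M,37,F,11.87
M,37,G,10.34
M,37,H,20.67
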