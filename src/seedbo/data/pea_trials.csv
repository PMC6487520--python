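index,trial,t1,t2,t3,t4,w1,w2,w3,y
1,1,24.7,21.5,24.2,22.6,200,200,200,0.73
2,1,24.6,19.8,24.5,24.1,200,195,213,0.41
3,1,25.9,22.0,25.1,22.0,200,182,203,0.69
4,2,24.9,21.4,24.2,23.0,200,200,197,0.49
5,2,25.1,24.8,26.8,27.8,196,3,179,0.82
6,2,23.0,21.3,27.8,26.6,187,208,206,0.66
7,3,24.7,21.6,24.3,22.4,200,197,207,0.69
8,3,25.0,22.5,24.3,21.4,200,195,202,0.51
9,3,20.6,26.7,29.3,28.8,178,9,179,0.54
10,4,25.1,24.8,26.8,27.8,196,3,179,0.87
11,4,21.7,26.2,28.6,28.6,182,8,179,0.91
12,4,26.5,27.7,25.7,26.6,159,10,169,0.77
13,5,21.6,26.3,28.7,28.6,182,8,179,0.81
14,5,25.6,21.7,24.3,22.1,204,189,201,0.58
15,5,26.0,21.8,25.8,26.8,195,178,227,0.78
16,6,28.2,24.1,26.6,28.9,228,18,235,0.73
17,6,27.5,24.7,24.0,30.1,23,95,248,0.54
18,6,30.4,21.0,34.3,23.7,24,10,250,0.67
19,7,26.4,22.2,29.9,25.6,170,39,144,0.89
20,7,25.8,23.7,29.6,25.2,173,39,162,1.13
21,7,25.8,25.7,30.2,25.5,249,45,108,0.69
22,8,22.4,22.4,32.4,25.2,127,52,201,0.7
23,8,23.3,22.3,31.6,26.0,139,52,188,0.98
24,8,21.0,20.6,30.1,23.2,146,30,186,0.55
25,9,24.0,23.9,32.7,24.5,125,61,194,0.87
26,9,24.2,23.2,31.8,25.0,136,54,184,0.97
27,9,25.7,24.7,32.7,26.6,138,73,188,0.77
28,10,22.4,20.8,29.6,23.3,147,18,164,0.78
29,10,23.0,21.6,29.8,24.0,150,27,166,1.0
30,10,22.7,22.5,29.8,22.7,156,26,172,0.69
31,11,24.0,21.6,28.9,23.6,160,28,157,0.68
32,11,24.1,22.0,29.0,23.9,162,32,160,1.1
33,11,24.0,22.4,29.0,23.1,167,32,165,0.92
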