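index,t1,t2,t3,t4,mean,sd
1,23.0,23.0,23.0,23.0,1.767,0.028
2,22.0,22.0,22.0,22.0,1.707,0.054
3,24.0,24.0,24.0,24.0,1.835,0.023
4,21.0,21.0,21.0,21.0,1.425,0.071
5,23.9,23.9,27.1,23.9,1.818,0.053
6,21.7,27.7,25.2,21.7,1.804,0.047
7,19.7,25.0,25.1,26.5,1.795,0.042
8,21.7,24.8,25.3,23.6,1.826,0.063
9,23.0,27.7,22.3,25.6,1.903,0.026
10,23.3,26.9,23.0,25.3,1.866,0.041
11,20.7,33.2,20.7,25.8,1.878,0.031
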