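20
0000000000
C 1.545248 0.119723 -0.035717
C 0.981959 1.470859 -0.338361
C -0.330075 1.732043 -0.390260
C -1.465550 0.754282 -0.162575
C 1.160624 -0.335496 1.335126
C -0.104916 -0.544243 1.718702
C -1.354384 -0.369588 0.878727
C 1.147171 -0.880502 -1.072776
C -0.121870 -1.230993 -1.315659
C -1.362745 -0.708726 -0.619484
H 2.653808 0.205578 -0.061335
H 1.677724 2.284118 -0.526255
H -0.623097 2.752003 -0.619480
H -2.490558 1.173499 -0.251725
H 1.953637 -0.505573 2.058292
H -0.264311 -0.874513 2.740575
H -2.315528 -0.596165 1.387822
H 1.932866 -1.347496 -1.660454
H -0.291316 -1.968746 -2.093941
H -2.328687 -1.130061 -0.971223
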