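g0001	GO:0003677
g0001	GO:0006259
g0002	GO:0005515
g0003	GO:0016301
g0003	GO:0007165
g0004	GO:0005488
g0005	GO:0006259
g0006	GO:0005515
g0006	GO:0009987
g0007	GO:0003676
g0008	GO:0016301
g0009	GO:0044237
g0010	GO:0005515
g0010	GO:0007165
g0011	GO:0003677
g0012	GO:0003824
g0013	GO:0008152
g0014	GO:0005515
g0015	GO:0016301
g0015	GO:0006259
g0016	GO:0003676
g0017	GO:0007165
g0018	GO:0003824
g0019	GO:0005488
g0019	GO:0009987
g0020	GO:0003677
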