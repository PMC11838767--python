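element,mass,abundance
C,12.0,0.9893
C,13.00335483507,0.0107
H,1.00782503207,0.999885
H,2.01410177812,0.000115
N,14.0030740048,0.99636
N,15.0001088989,0.00364
O,15.9949146196,0.99757
O,16.9991317565,0.00038
O,17.9991596129,0.00205
S,31.9720711744,0.9499
S,32.9714589098,0.0075
S,33.967867004,0.0425
S,35.96708071,0.0001
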