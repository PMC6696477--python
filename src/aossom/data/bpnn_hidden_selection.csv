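h,r2_min,r2_max,r2_mean,rmse_min,rmse_max,rmse_mean
6,0.627,0.906,0.793,15.794,26.600,21.351
7,0.382,0.810,0.678,18.841,37.911,25.515
8,0.450,0.845,0.630,18.955,31.600,26.440
9,0.280,0.824,0.690,18.190,40.136,25.424
10,0.512,0.832,0.650,17.906,36.760,27.188
11,0.503,0.804,0.716,28.880,34.671,24.384
12,0.568,0.832,0.704,18.252,30.010,24.299
13,0.391,0.867,0.726,17.611,33.872,23.202
14,0.127,0.848,0.599,16.768,55.106,32.411
15,0.561,0.812,0.681,18.927,40.192,27.247
16,0.300,0.857,0.672,17.897,37.628,25.187
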