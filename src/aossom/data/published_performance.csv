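model,r2,rmse,rpd,category
bpnn,0.880,14.916,2.837,A
svr,0.895,14.094,3.003,A
plsr,0.808,18.890,2.240,A
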