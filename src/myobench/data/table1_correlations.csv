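# Per-trial Pearson correlation coefficients between RMS envelopes of sEMG
# recorded simultaneously with wet Ag/AgCl and PPy fabric electrodes.
# 4 able-bodied subjects x 3 trials each (n = 12).
subject,trial,r
1,1,0.82
1,2,0.83
1,3,0.87
2,1,0.76
2,2,0.87
2,3,0.83
3,1,0.83
3,2,0.85
3,3,0.88
4,1,0.97
4,2,0.96
4,3,0.96
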