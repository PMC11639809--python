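video_id,duration,rr_ref,region,rr_video
1,00:26,32.31,total,32.05
1,00:26,32.31,r1,32.10
1,00:26,32.31,r2,31.75
1,00:26,32.31,r3,27.96
2,00:26,33.17,total,31.65
2,00:26,33.17,r1,31.59
2,00:26,33.17,r2,31.76
2,00:26,33.17,r3,31.72
3,00:26,30.00,total,29.69
3,00:26,30.00,r1,29.72
3,00:26,30.00,r2,28.04
3,00:26,30.00,r3,29.60
4,06:03,20.04,total,21.10
4,06:03,20.04,r1,22.02
4,06:03,20.04,r2,20.49
4,06:03,20.04,r3,23.12
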