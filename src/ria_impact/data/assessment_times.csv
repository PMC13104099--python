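tier,domain,mean_seconds
beginner,1,82
beginner,2,152
beginner,3,259
beginner,4,207
beginner,5,363
beginner,6,555
expert,1,65
expert,2,123
expert,3,229
expert,4,200
expert,5,216
expert,6,419
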