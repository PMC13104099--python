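domain,n_pairs,n_one_rating,n_no_rating,n_agree,n_disagree,pct_disagree,kappa,se,weighted_kappa,band
1,206,0,0,196,10,4.85,0.612,0.108,0.748,substantial
2,198,1,7,124,74,37.37,0.415,0.048,0.526,moderate
3,114,38,54,69,45,39.47,0.212,0.085,0.225,fair
4,104,39,63,96,8,7.69,0.516,0.148,0.516,moderate
5,104,38,64,68,36,34.61,0.280,0.080,0.306,fair
6,102,35,69,52,50,49.02,0.122,0.054,0.122,slight
overall,206,0,0,143,63,30.58,0.492,0.048,0.503,moderate
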