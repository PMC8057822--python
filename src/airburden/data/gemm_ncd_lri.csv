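age_bracket,theta,theta_lower,theta_upper,alpha,mu,nu
25-29,0.1585,0.129551,0.187449,1.6,15.5,36.8
30-34,0.1577,0.128888,0.186512,1.6,15.5,36.8
35-39,0.1570,0.128325,0.185675,1.6,15.5,36.8
40-44,0.1558,0.127380,0.184220,1.6,15.5,36.8
45-49,0.1532,0.125270,0.181130,1.6,15.5,36.8
50-54,0.1499,0.122578,0.177222,1.6,15.5,36.8
55-59,0.1462,0.119524,0.172876,1.6,15.5,36.8
60-64,0.1421,0.116130,0.168070,1.6,15.5,36.8
65-69,0.1374,0.112234,0.162566,1.6,15.5,36.8
70-74,0.1319,0.107714,0.156086,1.6,15.5,36.8
75-79,0.1253,0.102290,0.148310,1.6,15.5,36.8
80+,0.1141,0.093108,0.135092,1.6,15.5,36.8
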