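subject_id,age,egfr,acr,gender,group,cohort
52815,39,169.45,0.68,female,control,1
21206,39,94.85,1.11,female,control,1
52855,46,131.85,0.85,female,control,1
52805,47,145.27,0.47,female,control,1
21227,20,134.71,0.81,female,control,1
21246,24,74.53,0.51,female,control,1
21216,25,113.26,0.19,female,control,1
52778,70,134.61,0.3,female,control,1
52757,51,150.26,0.32,female,control,1
21225,50,119.12,0.35,female,control,1
52803,11,70.77,0.4,male,control,1
52833,26,153.98,1.6,male,control,1
52856,46,92.64,0.95,male,control,1
52839,47,120.56,1.06,male,control,1
52839,47,85.62,1.06,male,control,1
52777,57,160.36,1.03,male,control,1
52823,57,136.93,0.48,male,control,1
52818,66,145.09,0.67,male,control,1
21241,67,83.58,0.36,male,control,1
52861,68,102.38,1.71,male,control,1
52866,69,3,107.25,female,ckd,1
21245,28,29,8.27,female,ckd,1
52838,65,49,1.67,female,ckd,1
52973,49,51,30.68,female,ckd,1
52845,38,75,13.79,female,ckd,1
21240,39,92,119.93,female,ckd,1
52854,25,93,3.76,female,ckd,1
21244,35,99,11.23,female,ckd,1
52827,46,114,141.83,female,ckd,1
52871,60,123,82.99,female,ckd,1
52852,24,84.05,123.34,male,ckd,1
52840,41,123.38,10.61,male,ckd,1
52829,28,153.97,1925.38,male,ckd,1
52830,25,181.34,17.89,male,ckd,1
52842,48,11.04,2.69,male,ckd,1
52875,47,30.99,0.91,male,ckd,1
52842,48,11.04,2.69,male,ckd,1
52828,60,22.58,87.79,male,ckd,1
52862,60,54.94,3.05,male,ckd,1
52832,65,4.95,0.54,male,ckd,1
52768,33,185.43,1.32,female,control,2
52811,4,85.97,0.71,female,control,2
21213,14,92.56,0.52,female,control,2
21214,16,75.12,0.37,female,control,2
52812,16,68.11,2.51,female,control,2
21231,18,78.64,0.86,female,control,2
21229,20,129.93,0.76,female,control,2
21218,27,140.59,1.92,female,control,2
52825,62,153.39,1.84,female,control,2
21217,21,91.94,0.78,female,control,2
21210,17,72.7,0.26,male,control,2
21223,18,83.16,2.02,male,control,2
21232,21,165.3,1.24,male,control,2
21212,24,153.06,0.26,male,control,2
52804,33,217.41,1.21,male,control,2
21235,37,151.17,0.88,male,control,2
21243,48,123.11,1.14,male,control,2
52728,49,68.92,0.52,male,control,2
52759,59,85.61,0.89,male,control,2
52772,63,87.59,1.36,male,control,2
52865,65,1,0.68,female,ckd,2
52877,22,3,0.62,female,ckd,2
52834,71,11,0.91,female,ckd,2
21237,7,14,0.68,female,ckd,2
52859,30,17,1.04,female,ckd,2
21238,50,26,0.6,female,ckd,2
52867,71,35,0.53,female,ckd,2
21249,62,41,2.78,female,ckd,2
52857,28,46,46.4,female,ckd,2
52858,35,17,7.2,female,ckd,2
52843,22,157.26,2.55,male,ckd,2
52844,24,19.68,0.97,male,ckd,2
52864,28,5.37,5.03,male,ckd,2
52831,33,194.92,10,male,ckd,2
52873,35,24.3,1.2,male,ckd,2
52870,37,13.96,1.08,male,ckd,2
21248,39,5.92,2.08,male,ckd,2
52879,39,8.5,0.57,male,ckd,2
52835,44,5.15,4.33,male,ckd,2
52869,59,3.07,0.51,male,ckd,2
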