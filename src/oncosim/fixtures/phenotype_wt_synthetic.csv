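u,growth_rate_per_h,proliferation_time_h,lactate,glucose_uptake
0.0,0.0,inf,0.0,0.0
0.076,0.013863,50.0,0.02,0.314
0.305,0.034657,20.0,0.5,0.786
1.0,0.052912,13.1,1.8,1.2
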