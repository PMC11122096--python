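# Mechanical tissue parameters, NSCLC scenario.
# Labels: 0 other tissues, 1 tumor, 2 lung, 3 bone, 4 inner organs, 5 bronchi.
0: {name: other, E: 5.0e3, nu: 0.40}
1: {name: tumor, E: 10.0e3, nu: 0.40}
2: {name: lung, E: 5.0e3, nu: 0.40}
3: {name: bone, E: 1.0e9, nu: 0.30}
4: {name: inner_organs, E: 5.0e3, nu: 0.40}
5: {name: bronchi, E: 5.0e3, nu: 0.40}
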