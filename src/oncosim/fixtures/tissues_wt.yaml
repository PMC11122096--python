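# Mechanical tissue parameters, Wilms-tumor scenario.
# Labels: 0 other tissues, 1 tumor, 2 healthy kidney, 3 bone.
0: {name: other, E: 5.0e3, nu: 0.40}
1: {name: tumor, E: 20.0e3, nu: 0.40}
2: {name: healthy_kidney, E: 5.3e3, nu: 0.40}
3: {name: bone, E: 1.0e9, nu: 0.30}
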