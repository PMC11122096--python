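# Preoperative combination chemotherapy, Wilms-tumor scenario: 4 weekly
# vincristine administrations with actinomycin D in weeks 1 and 3
# (single-agent literature CKRs 0.28 and 0.4).
- {time_h: 0.0, modality: chemo, drug: vincristine, ckr: 0.28}
- {time_h: 0.0, modality: chemo, drug: actinomycin, ckr: 0.40}
- {time_h: 168.0, modality: chemo, drug: vincristine, ckr: 0.28}
- {time_h: 336.0, modality: chemo, drug: vincristine, ckr: 0.28}
- {time_h: 336.0, modality: chemo, drug: actinomycin, ckr: 0.40}
- {time_h: 504.0, modality: chemo, drug: vincristine, ckr: 0.28}
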