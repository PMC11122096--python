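# Radiotherapy schedule, NSCLC scenario: 4 fractions of 15 Gy, once a day,
# three days per week.
- {time_h: 0.0, modality: radio, dose_gy: 15.0}
- {time_h: 24.0, modality: radio, dose_gy: 15.0}
- {time_h: 48.0, modality: radio, dose_gy: 15.0}
- {time_h: 168.0, modality: radio, dose_gy: 15.0}
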