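year,trial_applications,trial_approvals
2020,1099,879
2021,1830,1483
2022,1829,1579
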