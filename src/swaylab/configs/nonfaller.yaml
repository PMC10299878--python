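duration: 30.0
fs: 100.0
lambda_ap: 0.007567481358383149
lambda_ml: 0.005000000000000002
n_trials: 3
sigma_ap: 2.029659598134316
sigma_ml: 1.000166149060849
subject_cv: 0.28
tremor_amp_ap: 4.234972523089943
tremor_amp_ml: 4.062789410580401
tremor_freq: 0.32
tremor_freq_sd: 0.15
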