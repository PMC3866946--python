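# Default synthetic cohort: 199 patients with the marginal structure the
# analysis assumes (age 32.0 +/- 4.2 y, infertility median 5 y with IQR
# 3-7, group pregnancy rates calibrated to 28.6% / 53.0%).
n_patients: 199
age_mean: 32.0
age_sd: 4.2
infertility_median: 5.0
infertility_iqr: [3.0, 7.0]
prior_pregnancy_prob: 0.32
target_rate_low: 0.286
target_rate_high: 0.530
efi_cutoff: 6
thaw_pregnancy_prob: 0.21
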