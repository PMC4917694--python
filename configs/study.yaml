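# Study-replica configuration: 52 healthy subjects (104 normal eyes) and
# 22 asymmetric-keratoconus patients (22 keratoconic + 22 fellow eyes).
n_normal_subjects: 52
n_asym_kc_subjects: 22
seed: 7
rho: 0.5            # intra-patient correlation of latent severity
holm: false         # post hoc Mann-Whitney p-values unadjusted
truncate_ci: true   # report Wald CIs truncated to [0, 1]
use_gam: true       # transform non-monotone markers before ROC
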