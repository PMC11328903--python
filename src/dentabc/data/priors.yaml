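# Default parameter priors for the 14 demographic models.
# Sizes are effective numbers of gene copies; times T_s1/T_s2 are in ka;
# m_* are per-lineage per-generation migration probabilities; mu is the
# per-generation phenotypic mutation rate shared by all traits.
N_cW: {distribution: loguniform, minimum: 10, maximum: 5000}
N_cE: {distribution: loguniform, minimum: 10, maximum: 5000}
N_mpW: {distribution: loguniform, minimum: 500, maximum: 50000}
N_mpE: {distribution: loguniform, minimum: 500, maximum: 50000}
N_lpW: {distribution: loguniform, minimum: 100, maximum: 50000}
N_lpE: {distribution: loguniform, minimum: 100, maximum: 50000}
N_hW: {distribution: loguniform, minimum: 500, maximum: 100000}
N_hE: {distribution: loguniform, minimum: 500, maximum: 100000}
N_s: {distribution: loguniform, minimum: 100, maximum: 50000}
N_gs1: {distribution: loguniform, minimum: 100, maximum: 50000}
N_gs2: {distribution: loguniform, minimum: 100, maximum: 50000}
P_lgm: {distribution: uniform, minimum: 0.0, maximum: 1.0}
T_s1: {distribution: uniform, minimum: 14.7, maximum: 19.0}
T_s2: {distribution: uniform, minimum: 28.0, maximum: 37.0}
p_holo: {distribution: uniform, minimum: 0.0, maximum: 1.0}
m_mp: {distribution: loguniform, minimum: 1.0e-6, maximum: 1.0e-3}
m_lp: {distribution: loguniform, minimum: 1.0e-6, maximum: 1.0e-3}
m_lg: {distribution: loguniform, minimum: 1.0e-6, maximum: 1.0e-3}
mu: {distribution: uniform, minimum: 2.6e-4, maximum: 5.0e-2}
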