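# Moderate-sedation (MOAA/S < 4) NLMAZ surface parameters, estimated from
# a gastrointestinal-endoscopy sedation cohort (56 patients / 227 pooled
# observations).  Units: C50 midazolam & alfentanil ng/mL, propofol ug/mL.
# Gamma terms use the ordered-pair convention (m,a), (m,p), (a,p) with
# (x_i - x_j) = first minus second.  The n-polynomial interaction terms
# were reported only as rounded zeros (true magnitude 1e-4 to 1e-7) and
# are carried as exactly zero here.
c50_mid: 40.73
c50_alf: 340.84
c50_prop: 1.21
u50_alpha_m: -0.34
u50_alpha_a: -0.65
u50_alpha_p: -0.50
u50_beta_ma: -0.65
u50_beta_mp: -0.40
u50_beta_ap: -0.75
u50_gamma_ma: -0.04
u50_gamma_mp: -0.04
u50_gamma_ap: -0.04
u50_delta_map: -0.65
n_alpha_m: 3.95
n_alpha_a: 13.40
n_alpha_p: 10.66
n_beta_ma: 0.0
n_beta_mp: 0.0
n_beta_ap: 0.0
n_gamma_ma: 0.0
n_gamma_mp: 0.0
n_gamma_ap: 0.0
n_delta_map: 0.0
link_u50: exp
link_n: identity
single_drug_reduction: true
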