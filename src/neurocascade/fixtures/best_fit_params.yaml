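# Best-fit cascade parameters (packaged defaults).
#
# The influx is a unit placeholder: it is not experimentally estimable and
# is calibrated against labeling-curve data at run time (see
# neurocascade.inference.calibrate_influx).  Shape parameters of stages
# whose fitted shape is not reported, and NSC minimum durations, use the
# package defaults documented in docs/methods.md.
influx: 1.0
min_divisions_anp: 1
max_divisions_anp: 4
renewal_prob_anp: 0.1
t_g1_anp_mean: 12.0
t_g1_anp_shape: 9.0
t_g1_anp_min: 3.0
t_s_anp_mean: 12.0
t_s_anp_shape: 22.0
t_s_anp_min: 4.0
t_g2m_anp_mean: 1.0
t_g2m_anp_shape: 12.0
t_g2m_anp_min: 0.5
t_anp_nb_mean: 12.0
t_anp_nb_shape: 9.0
t_anp_nb_min: 3.0
t_anp_apop_mean: 48.0
t_anp_apop_shape: 9.0
t_anp_apop_min: 2.0
t_nb_mean: 260.0
t_nb_shape: 2.0
t_nb_min: 20.0
t_apop_mean: 1.4
t_apop_shape: 9.0
t_apop_min: 0.15
d_g1: 0.14
d_s: 0.0
d_g2m: 0.02
d_anp: 0.33
d_nb: 0.97
min_divisions_nsc: 2
max_divisions_nsc: 5
renewal_prob_nsc: 0.57
t_g1_nsc_mean: 28.0
t_g1_nsc_shape: 9.0
t_g1_nsc_min: 3.0
t_s_nsc_mean: 11.0
t_s_nsc_shape: 22.0
t_s_nsc_min: 4.0
t_g2m_nsc_mean: 3.0
t_g2m_nsc_shape: 12.0
t_g2m_nsc_min: 0.5
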