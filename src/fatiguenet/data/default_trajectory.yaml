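# Ground-truth fatigue trajectory for the synthetic generator.
#
# slow_fast_gain multiplies theta/alpha1/alpha2 amplitudes relative to beta;
# it drives the (theta+alpha1+alpha2)/beta ratio.  alpha1_coupling is the
# variance share of a globally shared alpha1 source in the task condition.
# Both rise monotonically T0->T3 and dip at T4 (late-session release).
# The resting condition keeps a constant baseline coupling, so only the
# alpha1/task cell carries a time effect.
#
# The background field is stationary: all rhythms share a distance-decaying
# inter-channel correlation rho0(d) = spatial_rho_max * exp(-(d/spatial_scale)^2)
# over schematic 10-20 head coordinates, and each subject draws fixed
# per-channel coupling weights u_ch ~ U(1-h, 1+h), h = coupling_heterogeneity.
time_points: [T0, T1, T2, T3, T4]
slow_fast_gain: [1.00, 1.12, 1.24, 1.36, 1.30]
alpha1_coupling: [0.10, 0.22, 0.34, 0.46, 0.38]
rest_alpha1_coupling: 0.10
coupling_heterogeneity: 0.5
# Optional extra ingredient: a share of the fatigue-related synchronisation can
# be routed through disorder_rank extra shared sources with random per-subject
# loadings instead of the single global source.  Off by default.
coupling_disorder: 0.0
disorder_rank: 8
spatial_rho_max: 0.85
spatial_scale: 1.1
band_amplitude:
  delta: 8.0
  theta: 6.0
  alpha1: 9.0
  alpha2: 6.0
  beta: 5.0
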