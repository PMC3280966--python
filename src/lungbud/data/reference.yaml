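# Calibrated reference configuration: dimensionless kinetic point
# (lateral-branching class) and the idealised bud geometry with the
# elongated reference stalk used for steady-state classification.
# Lfar: 0 means 'apply the far-field buffer rule sqrt(D_cav*t_max)'.
bc:
  kind: open_farfield
  t_max: 400.0
geometry:
  Lfar: 0.0
  Rc: 2.0
  h0: 6.0
  rc: 1.0
  we: 0.2
hmax: 0.2
params:
  D_cav: 40.0
  D_f: 5.0
  D_p: 0.02
  D_s: 1.0
  Gamma: 0.1
  K_f: 1.0
  K_s: 1.0
  delta_c: 1.0
  delta_f: 5.0
  delta_p: 0.6
  delta_s: 0.2
  k_off: 1.0
  k_on: 1.0
  m_P: 2
  n: 2
  n_S: 1
  nu_f: 5.0
  nu_s: 1600.0
  rho0: 1.6
  rho1: 3.5
seed: 1
steady_tol: 1.0e-06
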