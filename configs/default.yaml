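# Full flat key-value configuration with the shipped defaults.
# Any subset of keys may be overridden; unknown keys are rejected.
K: 1.0
a1: 11.0
a2: 1.0
a3: 8.0
alpha0: 1.0
beta0: 0.06
beta10: 0.45
c_const: 0.3
c_off: 0.0
c_on: 0.9
dt: 0.01
eta0: 25.0
gamma0: 0.065
gamma1: 1.2
init_width: 0.05
init_x: 0.05
init_y: 0.2
k: 3.5
mode: constant
n: 2.0
nx: 100
ny: 100
phi0: 0.11
phi1: 0.45
preheat_tol: 0.001
q0_frac: 0.08
sigma: 0.0008
t0: 0.0
tau_off: 7.0
tau_on: 7.0
v0: 1.0
y0_off: 0.2
y0_on: 0.8
y_star: 0.5
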