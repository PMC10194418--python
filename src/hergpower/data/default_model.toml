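# Default wild-type hERG (IKr) two-gate model and variant presets.
# Rate law: r(V) = a * exp(b * V), a in ms^-1, b in mV^-1 (b signed).
#
# version 1: simplified Hodgkin-Huxley IKr formulation
#   I = g_max * a^4 * i * (V - e_rev)
# with a slow activation gate a (alpha = activation / beta = deactivation)
# raised to the classic delayed-rectifier fourth power to reproduce the
# sigmoidal onset of hERG activation (the channel opens through a chain of
# closed states), and a fast inactivation gate i (alpha = recovery from
# inactivation / beta = inactivation).  Kinetics sit at the slow end of
# reported whole-cell hERG values at 37 degC (activation tau ~350 ms at
# +20 mV, deactivation tau ~400 ms at -80 mV, recovery tau ~30 ms at
# -40 mV, sub-millisecond inactivation at the plateau): in this regime the
# current is far from quasi-static during a 300 ms action potential, which
# is the regime in which cooling visibly truncates current development and
# time dilation of the command compensates for it.  g_max is an effective
# amplitude scale (AP-clamp currents identify only g_max times the small
# residual gate occupancy), set so the wild-type 37 degC repolarization
# power is ~22 pA.s.

version = 1

[model]
label = "WT hERG two-gate IKr v1"
g_max = 500.0         # nS, effective amplitude scale (see note above)
e_rev = -88.0         # mV, K+ reversal under physiological gradients
t_ref = 37.0          # degC
q10_conductance = 1.4
activation_exponent = 4

# Per-process temperature coefficients.  The measured whole-cell band for
# the four gating rates is 1.7-2.6 with no published per-process mapping;
# the default assigns the band midpoint 2.2 uniformly, which is also the
# regime in which a single time-dilation factor can compensate cooling (the
# premise the correction validates).  Each entry is config-overridable.
[model.q10_rates]
activation = 2.2
deactivation = 2.2
inactivation = 2.2
recovery = 2.2

[model.activation]
alpha = [7.0e-4, 0.07]     # activation (opening)
beta = [2.27e-4, -0.03]    # deactivation
v_offset = 0.0

[model.inactivation]
alpha = [1.0e-2, -0.02]    # recovery from inactivation
beta = [3.0e-1, 0.09]      # inactivation
v_offset = 0.0

[variants.WT]
conductance_scale = 1.0
inactivation_vhalf_shift = 0.0
[variants.WT.rate_scales]
activation = 1.0
deactivation = 1.0
inactivation = 1.0
recovery = 1.0

# Loss-of-function, acquired-LQTS-linked: reduced functional conductance.
[variants.R328C]
conductance_scale = 0.3
inactivation_vhalf_shift = 0.0
[variants.R328C.rate_scales]
activation = 1.0
deactivation = 1.0
inactivation = 1.0
recovery = 1.0

# Gain-of-function, SQTS-linked: depolarizing shift of inactivation and
# faster recovery, so more current flows during the plateau.
[variants.D591H]
conductance_scale = 1.0
inactivation_vhalf_shift = 30.0
[variants.D591H.rate_scales]
activation = 1.0
deactivation = 1.0
inactivation = 1.0
recovery = 2.0
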