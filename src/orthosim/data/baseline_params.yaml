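# Baseline stochastic inputs for the ring-fenced elective orthopaedic unit.
# Length-of-stay means/SDs are in days; the model converts them to lognormal
# parameters by moment matching. prop_delayed is the probability a patient's
# whole stay is drawn from the delayed-discharge distribution.
los_specs:
  p_thr: {mean: 4.4, sd: 2.9}
  p_tkr: {mean: 4.7, sd: 2.8}
  p_ukr: {mean: 2.9, sd: 2.1}
  r_thr: {mean: 6.9, sd: 7.0}
  r_tkr: {mean: 7.2, sd: 7.6}
delayed_los: {mean: 16.5, sd: 15.1}
prop_delayed: 0.076
case_mix:
  primary: 0.87
  revision: 0.13
  within_primary: {p_thr: 0.51, p_tkr: 0.38, p_ukr: 0.11}
  within_revision: {r_thr: 0.55, r_tkr: 0.45}
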