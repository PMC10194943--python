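# Desk-scale demo: six rats, 45-minute recordings with a faster clamp
# descent so euglycemic, hypoglycemic and severe-hypoglycemic segments all
# occur, and a reduced clustering grid. Completes in a few minutes on one
# CPU; fully deterministic under the seed.
outdir: demo_output
seed: 7

sim:
  n_rats: 6
  frac_diabetic: 0.5
  frac_died: 0.3333333333333333
  duration_min: 45.0
  clamp_descent_min: 25.0

senator_list: [100]
cluster_list: [3, 5, 10]
time_list: [none]
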