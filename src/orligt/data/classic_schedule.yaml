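# Classic IGT payoff schedule (canonical Bechara-style magnitudes).
# One block per deck: constant gain per draw plus the cyclic loss list
# (position i of the list is served on draws i, i+10, i+20, ...).
A:
  gain_per_draw: 100.0
  loss_events: [0.0, 0.0, 150.0, 0.0, 300.0, 0.0, 200.0, 0.0, 250.0, 350.0]
B:
  gain_per_draw: 100.0
  loss_events: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1250.0, 0.0]
C:
  gain_per_draw: 50.0
  loss_events: [0.0, 0.0, 50.0, 0.0, 50.0, 0.0, 50.0, 0.0, 50.0, 50.0]
D:
  gain_per_draw: 50.0
  loss_events: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 250.0]
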