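# Scenario 4: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario4
description: Toxicity-only scenario for MTDC finding (target 0.30)
phiT_metric: 0.3
rawA: [1, 2, 3, 4, 5]
rawB: [1, 2, 3]
tox:
- [0.05, 0.1, 0.15, 0.3, 0.45]
- [0.1, 0.15, 0.3, 0.45, 0.55]
- [0.15, 0.3, 0.45, 0.5, 0.6]
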