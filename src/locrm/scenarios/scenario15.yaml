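# Scenario 15: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario15
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.15, 0.21, 0.3, 0.42, 0.44]
- [0.24, 0.3, 0.42, 0.44, 0.51]
- [0.3, 0.33, 0.44, 0.51, 0.55]
eff:
- [0.21, 0.15, 0.12, 0.09, 0.05]
- [0.6, 0.45, 0.33, 0.24, 0.21]
- [0.45, 0.31, 0.24, 0.21, 0.17]
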