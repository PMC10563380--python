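# Scenario 10: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario10
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.02, 0.04, 0.07, 0.12, 0.18]
- [0.04, 0.08, 0.13, 0.18, 0.25]
- [0.14, 0.25, 0.25, 0.25, 0.25]
eff:
- [0.1, 0.3, 0.45, 0.3, 0.08]
- [0.25, 0.45, 0.6, 0.45, 0.23]
- [0.2, 0.3, 0.45, 0.3, 0.16]
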