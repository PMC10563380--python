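# Scenario 7: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario7
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.05, 0.15, 0.3, 0.45, 0.55]
- [0.15, 0.3, 0.45, 0.55, 0.65]
- [0.3, 0.45, 0.55, 0.65, 0.75]
eff:
- [0.05, 0.25, 0.5, 0.55, 0.6]
- [0.25, 0.5, 0.55, 0.6, 0.65]
- [0.5, 0.55, 0.6, 0.65, 0.7]
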