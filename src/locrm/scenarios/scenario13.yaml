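# Scenario 13: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario13
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.05, 0.09, 0.14, 0.23, 0.3]
- [0.11, 0.15, 0.17, 0.24, 0.42]
- [0.14, 0.18, 0.23, 0.41, 0.46]
eff:
- [0.1, 0.18, 0.25, 0.3, 0.31]
- [0.2, 0.28, 0.35, 0.5, 0.52]
- [0.23, 0.3, 0.5, 0.52, 0.53]
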