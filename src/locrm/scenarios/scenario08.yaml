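# Scenario 8: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario8
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.1, 0.15, 0.21, 0.3, 0.42]
- [0.15, 0.24, 0.3, 0.42, 0.44]
- [0.2, 0.3, 0.42, 0.44, 0.51]
eff:
- [0.1, 0.18, 0.35, 0.5, 0.52]
- [0.15, 0.35, 0.5, 0.52, 0.53]
- [0.2, 0.5, 0.52, 0.54, 0.56]
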