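# Scenario 12: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario12
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.05, 0.09, 0.17, 0.24, 0.3]
- [0.15, 0.19, 0.23, 0.35, 0.42]
- [0.34, 0.38, 0.43, 0.51, 0.66]
eff:
- [0.2, 0.29, 0.55, 0.2, 0.15]
- [0.3, 0.39, 0.55, 0.25, 0.2]
- [0.36, 0.35, 0.3, 0.23, 0.2]
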