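# Scenario 16: true dose-outcome probabilities (rows = drug B levels, columns = drug A levels).
name: scenario16
description: Toxicity-efficacy scenario for OBDC finding (toxicity limit 0.35)
phiT_metric: 0.35
rawA: [0.08, 0.16, 0.24, 0.32, 0.4]
rawB: [0.08, 0.16, 0.24]
tox:
- [0.5, 0.56, 0.65, 0.68, 0.72]
- [0.55, 0.62, 0.7, 0.72, 0.8]
- [0.6, 0.67, 0.75, 0.79, 0.85]
eff:
- [0.52, 0.62, 0.7, 0.76, 0.79]
- [0.55, 0.66, 0.74, 0.79, 0.82]
- [0.58, 0.7, 0.78, 0.82, 0.85]
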