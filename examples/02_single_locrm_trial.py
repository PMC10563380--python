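"""One simulated LOCRM trial, step by step.

Runs a single seeded maximum-tolerated-dose-combination trial on the
Scenario 1 toxicity surface (target DLT rate 0.30, 51 patients in
cohorts of three) and prints where patients were treated and which
combination the isotonic-regression selection picks.
"""

import numpy as np

from locrm import DesignConfig, load_scenario, run_locrm_trial

scenario = load_scenario("scenario1")
print("true toxicity (rows = drug A level, cols = drug B level):")
print(scenario.tox_true)
print("true MTDCs (toxicity exactly 0.30):", sorted(scenario.mtdc_set))

result = run_locrm_trial(scenario, DesignConfig(), seed=1)
print("\npatients per dose after the trial:")
print(result.n)
print("DLTs per dose:")
print(result.yT)
print(f"enrolled: {result.enrolled}, stop reason: {result.stop_reason}")
print(f"selected MTDC: {result.selection}")
print("a selection inside", sorted(scenario.mtdc_set),
      "counts as a correct trial in the operating characteristics")
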