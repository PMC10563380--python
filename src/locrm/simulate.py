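"""Outcome generation, trial replication and operating characteristics.

Patient outcomes are independent Bernoulli draws against the
scenario's true per-dose probabilities (toxicity and response are
generated independently; scenarios specify marginals only).  A study
replays many independently seeded trials of one design on one scenario
and aggregates the usual operating characteristics: selection
percentages and mean patient numbers at the target doses, at the
overly toxic doses and (for dose-optimization runs) at the target dose
combinations, plus the early-stopping rate.

Per-trial seeds are spawned deterministically from the base seed, so
results are identical whether trials run serially or across workers.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .design import DesignConfig, TrialResult, run_locrm_trial
from .scenario import Scenario

__all__ = ["OperatingCharacteristics", "simulate_cohort", "run_study"]


@dataclass(frozen=True)
class OperatingCharacteristics:
    design: str
    scenario: str
    n_trials: int
    sel_pct_target: float      # % of trials selecting a true MTDC (LOCRM) / OBDC (LOCRM12)
    pts_at_target: float       # mean patients treated at those doses
    sel_pct_overdose: float
    pts_at_overdose: float
    sel_pct_tdc: float | None  # LOCRM12 only
    pts_at_tdc: float | None
    early_stop_pct: float      # % of trials ending with no selection
    pts_not_enrolled: float    # mean budget left unused
    mean_enrolled: float

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_cohort(scenario: Scenario, dose, cohort_size: int, rng):
    """Draw (DLT count, response count) for one cohort at ``dose``."""
    j, k = dose
    if not scenario.grid.contains(dose):
        raise ValueError(f"dose {dose!r} outside scenario grid")
    dlt = int(rng.binomial(cohort_size, scenario.tox_true[j - 1, k - 1]))
    resp = 0
    if scenario.eff_true is not None:
        resp = int(rng.binomial(cohort_size, scenario.eff_true[j - 1, k - 1]))
    return dlt, resp


def _run_one(design: str, scenario: Scenario, cfg: DesignConfig, seed) -> TrialResult:
    if design == "locrm":
        return run_locrm_trial(scenario, cfg, seed)
    if design == "locrm12":
        from .design12 import run_locrm12_trial
        return run_locrm12_trial(scenario, cfg, seed)
    raise ValueError(f"unknown design {design!r}")


def run_study(design: str, scenario: Scenario, cfg: DesignConfig | None = None,
              n_trials: int = 1000, base_seed: int = 0, workers: int = 1):
    """Replicate one design on one scenario.

    Returns ``(oc, records)``: the aggregated operating characteristics
    and a per-trial DataFrame.  ``base_seed`` fixes the whole study;
    per-trial seeds are spawned from it independently of ``workers``.
    """
    if cfg is None:
        cfg = DesignConfig() if design == "locrm" else DesignConfig.for_locrm12()
    seeds = np.random.SeedSequence(base_seed).spawn(n_trials)
    if workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=workers)(
            delayed(_run_one)(design, scenario, cfg, s) for s in seeds)
    else:
        results = [_run_one(design, scenario, cfg, s) for s in seeds]

    target = scenario.mtdc_set if design == "locrm" else scenario.obdc_set
    overdoses = scenario.overdose_set
    tdcs = scenario.tdc_set if (design == "locrm12"
                                and scenario.eff_true is not None) else None

    rows = []
    for i, r in enumerate(results):
        rows.append({
            "trial": i,
            "sel_j": r.selection[0] if r.selection else 0,
            "sel_k": r.selection[1] if r.selection else 0,
            "selected_target": r.selection in target,
            "selected_overdose": r.selection in overdoses,
            "selected_tdc": (r.selection in tdcs) if tdcs is not None else False,
            "no_selection": r.selection is None,
            "stop_reason": r.stop_reason,
            "enrolled": r.enrolled,
            "pts_at_target": r.patients_at(target),
            "pts_at_overdose": r.patients_at(overdoses),
            "pts_at_tdc": r.patients_at(tdcs) if tdcs is not None else 0,
        })
    records = pd.DataFrame(rows)
    oc = OperatingCharacteristics(
        design=design, scenario=scenario.name, n_trials=n_trials,
        sel_pct_target=100.0 * records["selected_target"].mean(),
        pts_at_target=float(records["pts_at_target"].mean()),
        sel_pct_overdose=100.0 * records["selected_overdose"].mean(),
        pts_at_overdose=float(records["pts_at_overdose"].mean()),
        sel_pct_tdc=(100.0 * records["selected_tdc"].mean()
                     if tdcs is not None else None),
        pts_at_tdc=(float(records["pts_at_tdc"].mean())
                    if tdcs is not None else None),
        early_stop_pct=100.0 * records["no_selection"].mean(),
        pts_not_enrolled=float((cfg.Nmax - records["enrolled"]).mean()),
        mean_enrolled=float(records["enrolled"].mean()),
    )
    return oc, records
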