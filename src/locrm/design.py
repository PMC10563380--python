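"""The LOCRM trial engine: dose finding for the maximum tolerated combination.

One trial is a sequence of cohorts.  Each cohort is treated at the
current dose; after its DLT outcomes are observed the design

1. applies the beta-binomial overdose rule (upward-closed elimination;
   if the lowest dose (1,1) is eliminated the trial stops with no
   selection),
2. stops for selection once the patient budget is exhausted, and
3. otherwise refits the local Bayesian-model-averaged CRM on the
   neighbourhood A of the current dose and moves to the admissible
   dose whose averaged toxicity estimate is closest to the target,
   breaking exact ties at random.

At the end, the observed toxicity-rate matrix is smoothed by weighted
bivariate isotonic regression and the tried, non-eliminated dose whose
smoothed rate is closest to the target is declared the MTDC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .efficacy import EffPriors, MCMCConfig
from .grid import DoseGrid
from .isotonic import biviso
from .orderings import local_set
from .toxicity import ToxCounts, bma_estimates, safety_eliminate

__all__ = [
    "DesignConfig", "TrialState", "TrialResult",
    "next_dose_locrm", "update_and_check", "select_mtdc", "run_locrm_trial",
]

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class DesignConfig:
    """Design parameters shared by the LOCRM and LOCRM12 engines.

    Defaults are the MTDC-finding configuration (target 0.30,
    elimination cutoff 0.95, 51 patients in cohorts of three).
    ``for_locrm12`` switches to the dose-optimization configuration
    (looser toxicity limit 0.35 with cutoff 0.85, efficacy futility
    monitoring at phiE = 0.2 / cE = 0.9, a 21-patient start-up stage
    followed by a 30-patient model-guided main stage, exploration
    exponent z = 2).
    """

    phiT: float = 0.30
    cT: float = 0.95
    cohort: int = 3
    Nmax: int = 51
    halfwidth: float = 0.05
    prior_sd2: float = 2.0
    tox_prior: str = "normal"          # or "exponential"
    prior_mtd_rule: str = "n_minus_1"
    elim_min_n: int = 3
    # LOCRM12-only settings
    phiE: float = 0.20
    cE: float = 0.90
    z: float = 2.0
    n_startup: int = 21
    n_main: int = 30
    futility_min_n: int = 3
    eff_priors: EffPriors = field(default_factory=EffPriors)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    eff_local: str = "B"               # neighbourhood of the efficacy model
    explore_rule: str = "max_qbar"     # or "uniform"
    obdc_estimator: str = "model"      # or "empirical"

    @classmethod
    def for_locrm12(cls, **overrides) -> "DesignConfig":
        base = dict(phiT=0.35, cT=0.85, Nmax=51)
        base.update(overrides)
        return cls(**base)

    def replace(self, **overrides) -> "DesignConfig":
        return replace(self, **overrides)


@dataclass
class TrialState:
    """Accumulating counts and bookkeeping of a single trial."""

    grid: DoseGrid
    n: np.ndarray
    yT: np.ndarray
    yE: np.ndarray
    current: tuple = (1, 1)
    eliminated: set = field(default_factory=set)
    futile: set = field(default_factory=set)
    stage: str = "main"                # "startup" or "main" (LOCRM12)
    enrolled: int = 0
    enrolled_main: int = 0
    stopped: bool = False
    stop_reason: str | None = None

    @classmethod
    def fresh(cls, grid: DoseGrid, stage: str = "main") -> "TrialState":
        shape = (grid.J, grid.K)
        return cls(grid=grid, n=np.zeros(shape, int), yT=np.zeros(shape, int),
                   yE=np.zeros(shape, int), stage=stage)

    @property
    def tox_counts(self) -> ToxCounts:
        return ToxCounts(n=self.n, yT=self.yT)

    def tried(self) -> list:
        return [d for d in self.grid.doses() if self.n[d[0] - 1, d[1] - 1] > 0]

    def admissible(self, dose) -> bool:
        return dose not in self.eliminated and dose not in self.futile

    def record(self, dose, cohort: int, dlt: int, resp: int = 0):
        j, k = dose
        self.n[j - 1, k - 1] += cohort
        self.yT[j - 1, k - 1] += dlt
        self.yE[j - 1, k - 1] += resp
        self.enrolled += cohort
        if self.stage == "main":
            self.enrolled_main += cohort


@dataclass(frozen=True)
class TrialResult:
    selection: tuple | None
    stop_reason: str
    n: np.ndarray
    yT: np.ndarray
    yE: np.ndarray
    enrolled: int
    scenario: str = ""

    def patients_at(self, doses) -> int:
        return int(sum(self.n[j - 1, k - 1] for j, k in doses))


def _argmin_target(candidates, values, target, rng, prefer_low=False):
    """Candidate(s) minimizing |value - target|; random or low-index tie-break."""
    dist = {d: abs(values[d] - target) for d in candidates}
    best = min(dist.values())
    ties = [d for d in candidates if dist[d] <= best + _TIE_TOL]
    if len(ties) == 1:
        return ties[0]
    if prefer_low:
        return min(ties, key=lambda d: (d[0] + d[1], d[0]))
    return ties[int(rng.integers(len(ties)))]


def _deescalate_fallback(state: TrialState):
    """Nearest admissible dose componentwise <= current, or None.

    Used when every member of the local candidate set has been
    eliminated; elimination is upward-closed, so admissible doses, if
    any remain, lie below the current dose.
    """
    j0, k0 = state.current
    cands = [d for d in state.grid.doses()
             if d[0] <= j0 and d[1] <= k0 and state.admissible(d)]
    if not cands:
        return None
    return max(cands, key=lambda d: (d[0] + d[1], d[0]))


def next_dose_locrm(state: TrialState, cfg: DesignConfig, rng) -> tuple | None:
    """Allocation rule: admissible neighbour with BMA estimate closest to phiT."""
    ls = local_set(state.grid, state.current)
    candidates = [d for d in ls.A if state.admissible(d)]
    if not candidates:
        return _deescalate_fallback(state)
    post = bma_estimates(state.tox_counts, ls, prior_sd2=cfg.prior_sd2,
                         halfwidth=cfg.halfwidth, target=cfg.phiT,
                         prior=cfg.tox_prior, prior_mtd_rule=cfg.prior_mtd_rule)
    return _argmin_target(candidates, post.pbar, cfg.phiT, rng)


def update_and_check(state: TrialState, cfg: DesignConfig) -> TrialState:
    """Post-cohort bookkeeping: overdose elimination and stopping."""
    state.eliminated |= safety_eliminate(state.tox_counts, cfg.phiT, cfg.cT,
                                         cfg.elim_min_n)
    if (1, 1) in state.eliminated:
        state.stopped = True
        state.stop_reason = "all_toxic"
    elif state.enrolled >= cfg.Nmax:
        state.stopped = True
        state.stop_reason = "max_n"
    return state


def isotonic_tox_estimates(state: TrialState, cfg: DesignConfig) -> np.ndarray:
    """Bivariate isotonic smoothing of the observed DLT rates.

    Untried cells enter at the target rate with negligible weight so
    they do not distort the fit; they are excluded from selection
    anyway.
    """
    tried = state.n > 0
    rates = np.where(tried, state.yT / np.maximum(state.n, 1), cfg.phiT)
    weights = np.where(tried, state.n, 1e-6).astype(float)
    return biviso(rates, weights).fitted


def select_mtdc(state: TrialState, cfg: DesignConfig, rng=None) -> tuple | None:
    """Final MTDC: tried, non-eliminated dose with smoothed rate nearest phiT."""
    candidates = [d for d in state.tried() if d not in state.eliminated]
    if not candidates:
        return None
    fitted = isotonic_tox_estimates(state, cfg)
    values = {d: fitted[d[0] - 1, d[1] - 1] for d in candidates}
    return _argmin_target(candidates, values, cfg.phiT, rng, prefer_low=True)


def run_locrm_trial(scenario, cfg: DesignConfig, seed) -> TrialResult:
    """Simulate one complete LOCRM trial; fully reproducible by seed."""
    from .simulate import simulate_cohort  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    state = TrialState.fresh(scenario.grid, stage="main")
    state.current = (1, 1)
    while not state.stopped:
        dlt, resp = simulate_cohort(scenario, state.current, cfg.cohort, rng)
        state.record(state.current, cfg.cohort, dlt, resp)
        state = update_and_check(state, cfg)
        if state.stopped:
            break
        nxt = next_dose_locrm(state, cfg, rng)
        if nxt is None:
            state.stopped = True
            state.stop_reason = "no_admissible_dose"
            break
        state.current = nxt
    selection = None
    if state.stop_reason == "max_n":
        selection = select_mtdc(state, cfg, rng)
    return TrialResult(selection=selection, stop_reason=state.stop_reason,
                       n=state.n.copy(), yT=state.yT.copy(), yE=state.yE.copy(),
                       enrolled=state.enrolled, scenario=scenario.name)
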