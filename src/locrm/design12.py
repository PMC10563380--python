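"""The LOCRM12 trial engine: joint toxicity-efficacy dose optimization.

The design runs in two stages.  A model-free start-up stage escalates
quickly — after each DLT-free cohort the level of one randomly chosen
drug is raised by one — and hands over to the model-guided main stage
as soon as a DLT is seen in the most recent cohort (or the start-up
budget is spent).  In the main stage each decision

1. refits the local BMA-CRM toxicity model on the neighbourhood A and
   finds the local MTDC (j*, k*), the dose with averaged toxicity
   estimate closest to the toxicity limit phiT;
2. forms the admissible set: doses in A whose toxicity estimate does
   not exceed that of (j*, k*), minus eliminated and futile doses;
3. refits the robit efficacy model on the 9-dose neighbourhood B and
   flags futile doses (posterior mass below phiE exceeding cE);
4. picks the admissible dose (j+, k+) with the highest posterior-mean
   efficacy, but balances exploitation against exploration: when
   (j+, k+) has already been tried and untried admissible doses
   remain, it is only kept if its efficacy estimate beats the decaying
   cutoff ((N - n) / N)^z, where n counts main-stage patients and N is
   the main-stage budget; otherwise an untried admissible dose is
   explored.

At the end the OBDC is the tried dose with the highest estimated
efficacy among the safe set — doses whose isotonically smoothed
toxicity does not exceed that of the selected MTDC — excluding
anything eliminated for toxicity or futility.
"""

from __future__ import annotations

import numpy as np

from .design import (DesignConfig, TrialResult, TrialState, _argmin_target,
                     _deescalate_fallback, isotonic_tox_estimates)
from .efficacy import EffCounts, eff_posterior, futility_eliminate
from .orderings import local_set
from .toxicity import bma_estimates, safety_eliminate

__all__ = [
    "startup_next", "admissible_set", "next_dose_locrm12", "monitor",
    "select_obdc", "run_locrm12_trial",
]

_TOL = 1e-12


def startup_next(state: TrialState, cfg: DesignConfig, rng,
                 last_cohort_dlts: int):
    """Start-up decision: escalate one random drug, or hand over to main.

    Returns the next dose, or ``None`` to signal the stage transition
    (triggered by a DLT in the most recent cohort or an exhausted
    start-up budget).  At a boundary the other drug is escalated; at
    the top corner the dose is held.
    """
    if last_cohort_dlts > 0 or state.enrolled >= cfg.n_startup:
        return None
    j, k = state.current
    options = []
    if j < state.grid.J:
        options.append((j + 1, k))
    if k < state.grid.K:
        options.append((j, k + 1))
    if not options:                       # both drugs at top level: hold
        return (j, k)
    return options[int(rng.integers(len(options)))]


def admissible_set(tox_post, state: TrialState, star: tuple) -> list:
    """Doses in A with toxicity estimate at most that of the local MTDC."""
    thr = tox_post.pbar[star]
    return [d for d in tox_post.local.A
            if tox_post.pbar[d] <= thr + _TOL and state.admissible(d)]


def next_dose_locrm12(state: TrialState, tox_post, eff_post,
                      cfg: DesignConfig, rng, star: tuple):
    """Two-step exploitation/exploration allocation within the admissible set."""
    atilde = admissible_set(tox_post, state, star)
    if not atilde:
        return _deescalate_fallback(state)
    qbar = eff_post.qbar
    best_q = max(qbar[d] for d in atilde)
    ties = [d for d in atilde if qbar[d] >= best_q - _TOL]
    dagger = ties[int(rng.integers(len(ties)))]
    untried = [d for d in atilde if state.n[d[0] - 1, d[1] - 1] == 0]
    if dagger in untried or not untried:
        return dagger
    cutoff = (max(cfg.n_main - state.enrolled_main, 0) / cfg.n_main) ** cfg.z
    if qbar[dagger] > cutoff:
        return dagger
    if cfg.explore_rule == "uniform":
        return untried[int(rng.integers(len(untried)))]
    best_u = max(qbar[d] for d in untried)
    ties_u = [d for d in untried if qbar[d] >= best_u - _TOL]
    return ties_u[int(rng.integers(len(ties_u)))]


def monitor(state: TrialState, cfg: DesignConfig) -> TrialState:
    """Post-cohort safety/futility bookkeeping and stopping checks."""
    state.eliminated |= safety_eliminate(state.tox_counts, cfg.phiT, cfg.cT,
                                         cfg.elim_min_n)
    if (1, 1) in state.eliminated:
        state.stopped, state.stop_reason = True, "all_toxic"
    elif all(not state.admissible(d) for d in state.grid.doses()):
        state.stopped, state.stop_reason = True, "all_toxic_or_futile"
    elif state.enrolled >= cfg.Nmax:
        state.stopped, state.stop_reason = True, "max_n"
    return state


def _eff_estimates(state: TrialState, cfg: DesignConfig, rng) -> dict:
    """End-of-trial efficacy estimates over all tried doses."""
    tried = state.tried()
    if cfg.obdc_estimator == "empirical":
        return {d: state.yE[d[0] - 1, d[1] - 1] / state.n[d[0] - 1, d[1] - 1]
                for d in tried}
    post = eff_posterior(EffCounts(n=state.n, yE=state.yE), tried, state.grid,
                         priors=cfg.eff_priors, mcmc=cfg.mcmc, rng=rng)
    return post.qbar


def select_obdc(state: TrialState, cfg: DesignConfig, rng=None) -> tuple | None:
    """Final OBDC: most efficacious tried dose within the safe set."""
    tried_ok = [d for d in state.tried() if d not in state.eliminated]
    if not tried_ok:
        return None
    fitted = isotonic_tox_estimates(state, cfg)
    iso = {d: fitted[d[0] - 1, d[1] - 1] for d in tried_ok}
    mtdc = _argmin_target(tried_ok, iso, cfg.phiT, rng, prefer_low=True)
    safe = [d for d in tried_ok
            if iso[d] <= iso[mtdc] + _TOL and d not in state.futile]
    if not safe:
        return None
    qhat = _eff_estimates(state, cfg, rng)
    best = max(qhat[d] for d in safe)
    ties = [d for d in safe if qhat[d] >= best - _TOL]
    return min(ties, key=lambda d: (d[0] + d[1], d[0]))


def run_locrm12_trial(scenario, cfg: DesignConfig | None = None,
                      seed=None) -> TrialResult:
    """Simulate one complete LOCRM12 trial; fully reproducible by seed."""
    from .simulate import simulate_cohort

    if scenario.eff_true is None:
        raise ValueError("LOCRM12 requires a scenario with efficacy probabilities")
    if cfg is None:
        cfg = DesignConfig.for_locrm12()
    rng = np.random.default_rng(seed)
    state = TrialState.fresh(scenario.grid, stage="startup")
    state.current = (1, 1)
    while not state.stopped:
        dlt, resp = simulate_cohort(scenario, state.current, cfg.cohort, rng)
        state.record(state.current, cfg.cohort, dlt, resp)
        state = monitor(state, cfg)
        if state.stopped:
            break
        if state.stage == "startup":
            nxt = startup_next(state, cfg, rng, last_cohort_dlts=dlt)
            if nxt is not None:
                state.current = nxt
                continue
            state.stage = "main"       # seamless transition, dose unchanged
        # main-stage decision
        ls = local_set(state.grid, state.current)
        tox_post = bma_estimates(state.tox_counts, ls, prior_sd2=cfg.prior_sd2,
                                 halfwidth=cfg.halfwidth, target=cfg.phiT,
                                 prior=cfg.tox_prior,
                                 prior_mtd_rule=cfg.prior_mtd_rule)
        star = _argmin_target(list(ls.A), tox_post.pbar, cfg.phiT, rng)
        eff_doses = ls.B if cfg.eff_local == "B" else ls.A
        eff_counts = EffCounts(n=state.n, yE=state.yE)
        eff_post = eff_posterior(eff_counts, eff_doses, state.grid,
                                 priors=cfg.eff_priors, mcmc=cfg.mcmc, rng=rng)
        state.futile |= futility_eliminate(eff_post, cfg.phiE, cfg.cE,
                                           cfg.futility_min_n, eff_counts)
        if all(not state.admissible(d) for d in state.grid.doses()):
            state.stopped, state.stop_reason = True, "all_toxic_or_futile"
            break
        nxt = next_dose_locrm12(state, tox_post, eff_post, cfg, rng, star)
        if nxt is None:
            state.stopped, state.stop_reason = True, "no_admissible_dose"
            break
        state.current = nxt
    selection = None
    if state.stop_reason == "max_n":
        selection = select_obdc(state, cfg, rng)
    return TrialResult(selection=selection, stop_reason=state.stop_reason,
                       n=state.n.copy(), yT=state.yT.copy(), yE=state.yE.copy(),
                       enrolled=state.enrolled, scenario=scenario.name)
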