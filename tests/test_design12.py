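"""LOCRM12 engine: start-up, admissible set, allocation, monitoring, OBDC."""

import numpy as np
import pytest

from locrm import DesignConfig, load_scenario, run_locrm12_trial
from locrm.design import TrialState
from locrm.design12 import (admissible_set, monitor, next_dose_locrm12,
                            select_obdc, startup_next)
from locrm.efficacy import EffCounts, MCMCConfig, eff_posterior
from locrm.orderings import local_set
from locrm.toxicity import bma_estimates


@pytest.fixture
def cfg12():
    return DesignConfig.for_locrm12(mcmc=MCMCConfig(iters=600, burnin=300))


def state_with(grid, entries, current=(1, 1), stage="main"):
    st = TrialState.fresh(grid, stage=stage)
    st.current = current
    for (j, k), (n, yT, yE) in entries.items():
        st.n[j - 1, k - 1] = n
        st.yT[j - 1, k - 1] = yT
        st.yE[j - 1, k - 1] = yE
        st.enrolled += n
        if stage == "main":
            st.enrolled_main += n
    return st


class TestStartup:
    def test_dlt_free_cohort_escalates_one_random_drug(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (3, 0, 1)}, stage="startup")
        picks = {startup_next(st, cfg12, np.random.default_rng(s), 0)
                 for s in range(60)}
        assert picks == {(1, 2), (2, 1)}

    def test_dlt_triggers_transition(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (3, 1, 0)}, stage="startup")
        assert startup_next(st, cfg12, np.random.default_rng(0), 1) is None

    def test_budget_exhaustion_forces_transition(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (21, 0, 5)}, stage="startup")
        assert startup_next(st, cfg12, np.random.default_rng(0), 0) is None

    def test_boundary_escalates_other_drug(self, grid53, cfg12):
        st = state_with(grid53, {(5, 1): (3, 0, 1)}, current=(5, 1),
                        stage="startup")
        st.enrolled = 6
        assert startup_next(st, cfg12, np.random.default_rng(0), 0) == (5, 2)

    def test_top_corner_holds(self, grid53, cfg12):
        st = state_with(grid53, {(5, 3): (3, 0, 1)}, current=(5, 3),
                        stage="startup")
        st.enrolled = 6
        assert startup_next(st, cfg12, np.random.default_rng(0), 0) == (5, 3)


class TestAdmissibleSet:
    def test_star_always_admissible_and_filtering(self, grid53):
        st = state_with(grid53, {(2, 2): (6, 1, 2)}, current=(2, 2))
        ls = local_set(grid53, (2, 2))
        post = bma_estimates(st.tox_counts, ls, target=0.35)
        star = min(ls.A, key=lambda d: abs(post.pbar[d] - 0.35))
        atilde = admissible_set(post, st, star)
        assert star in atilde
        for d in atilde:
            assert post.pbar[d] <= post.pbar[star] + 1e-9
        st.eliminated = {star}
        assert star not in admissible_set(post, st, star)


class TestAllocation12:
    def _posteriors(self, grid, st, cfg):
        ls = local_set(grid, st.current)
        tox = bma_estimates(st.tox_counts, ls, target=cfg.phiT)
        eff = eff_posterior(EffCounts(n=st.n, yE=st.yE), ls.B, grid,
                            priors=cfg.eff_priors, mcmc=cfg.mcmc, rng=3)
        star = min(ls.A, key=lambda d: abs(tox.pbar[d] - cfg.phiT))
        return tox, eff, star

    def test_untried_best_dose_taken_directly(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (3, 0, 2)}, current=(1, 1))
        tox, eff, star = self._posteriors(grid53, st, cfg12)
        pick = next_dose_locrm12(st, tox, eff, cfg12, np.random.default_rng(0),
                                 star)
        assert pick in admissible_set(tox, st, star)

    def test_main_stage_start_forces_exploration(self, grid53, cfg12):
        """With no main-stage patients the cutoff is 1, so a tried optimum
        cannot be exploited while untried admissible doses remain."""
        st = state_with(grid53,
                        {(1, 1): (3, 0, 2), (1, 2): (3, 0, 2), (2, 1): (3, 0, 1)},
                        current=(1, 2))
        st.enrolled_main = 0
        tox, eff, star = self._posteriors(grid53, st, cfg12)
        pick = next_dose_locrm12(st, tox, eff, cfg12, np.random.default_rng(1),
                                 star)
        assert st.n[pick[0] - 1, pick[1] - 1] == 0

    def test_cutoff_arithmetic_allows_exploitation(self, grid53, cfg12):
        # halfway through the main stage with z=2 the cutoff is 0.25
        assert ((30 - 15) / 30) ** 2 == pytest.approx(0.25)

    def test_allocated_dose_is_admissible(self, grid53, cfg12):
        st = state_with(grid53, {(2, 2): (9, 2, 4), (2, 1): (6, 1, 2)},
                        current=(2, 2))
        st.enrolled_main = 15
        tox, eff, star = self._posteriors(grid53, st, cfg12)
        for s in range(10):
            pick = next_dose_locrm12(st, tox, eff, cfg12,
                                     np.random.default_rng(s), star)
            assert pick in admissible_set(tox, st, star)


class TestMonitor:
    def test_lowest_dose_elimination_stops(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (6, 6, 0)})
        st = monitor(st, cfg12)
        assert st.stopped and st.stop_reason == "all_toxic"

    def test_all_futile_stops(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (3, 0, 0)})
        st.futile = set(grid53.doses())
        st = monitor(st, cfg12)
        assert st.stopped and st.stop_reason == "all_toxic_or_futile"

    def test_budget_stop(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (51, 5, 10)})
        st = monitor(st, cfg12)
        assert st.stopped and st.stop_reason == "max_n"


class TestSelectObdc:
    def test_single_safe_dose_selected(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (12, 2, 6)})
        assert select_obdc(st, cfg12, np.random.default_rng(0)) == (1, 1)

    def test_untried_dose_never_selected(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (9, 1, 3), (2, 1): (9, 2, 5)})
        sel = select_obdc(st, cfg12, np.random.default_rng(0))
        assert st.n[sel[0] - 1, sel[1] - 1] > 0

    def test_futile_dose_never_selected(self, grid53, cfg12):
        st = state_with(grid53, {(1, 1): (9, 1, 3), (2, 1): (9, 2, 8)})
        st.futile = {(2, 1)}
        assert select_obdc(st, cfg12, np.random.default_rng(0)) == (1, 1)

    def test_empirical_estimator_picks_highest_observed_rate(self, grid53):
        cfg = DesignConfig.for_locrm12(obdc_estimator="empirical")
        st = state_with(grid53, {(1, 1): (9, 1, 2), (2, 1): (9, 2, 7),
                                 (1, 2): (9, 2, 4)})
        assert select_obdc(st, cfg, np.random.default_rng(0)) == (2, 1)


class TestTrial12:
    def test_seed_reproducibility(self, cfg12):
        scen = load_scenario("scenario7")
        a = run_locrm12_trial(scen, cfg12, 5)
        b = run_locrm12_trial(scen, cfg12, 5)
        assert a.selection == b.selection and np.array_equal(a.n, b.n)

    def test_budget_and_no_allocation_to_flagged_doses(self, cfg12):
        scen = load_scenario("scenario8")
        for seed in range(4):
            r = run_locrm12_trial(scen, cfg12, seed)
            assert r.enrolled <= 51

    def test_requires_efficacy_scenario(self, cfg12):
        with pytest.raises(ValueError):
            run_locrm12_trial(load_scenario("scenario1"), cfg12, 0)

    def test_all_toxic_scenario_mostly_stops_early(self, cfg12):
        scen = load_scenario("scenario16")
        stops = sum(run_locrm12_trial(scen, cfg12, s).selection is None
                    for s in range(40))
        assert stops / 40 > 0.75
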