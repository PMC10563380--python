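"""Per-ordering CRM posterior, Bayesian model averaging, overdose rule."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from locrm import (DoseGrid, ToxCounts, bma_estimates, enumerate_orderings,
                   generate_skeleton, local_set, safety_eliminate, tox_prob)
from locrm.toxicity import ordering_posterior


def trapezoid_oracle(counts, ls, skeleton, ordering, prior_sd2):
    """Dense trapezoid-rule reference for the 1-D posterior integrals."""
    a = np.linspace(-10, 10, 20001)
    pi = np.array([skeleton[ordering.rank(d)] for d in ls.A])
    probs = pi[:, None] ** np.exp(a)[None, :]
    log_lik = np.zeros_like(a)
    with np.errstate(divide="ignore"):
        for i, d in enumerate(ls.A):
            n, y = counts.at(d)
            if y > 0:
                log_lik += y * np.log(probs[i])
            if n - y > 0:
                log_lik += (n - y) * np.log1p(-probs[i])
    dens = np.exp(log_lik) * np.exp(-0.5 * a**2 / prior_sd2) / math.sqrt(
        2 * math.pi * prior_sd2)
    marginal = np.trapezoid(dens, a)
    means = {d: np.trapezoid(probs[i] * dens, a) / marginal
             for i, d in enumerate(ls.A)}
    return marginal, means


@pytest.fixture
def setup53(grid53):
    ls = local_set(grid53, (3, 2))
    skel = generate_skeleton(0.3, 5, 4, 0.05)
    ordering = enumerate_orderings(ls)[0]
    return ls, skel, ordering


def counts_on(grid, entries):
    n = np.zeros((grid.J, grid.K), int)
    y = np.zeros((grid.J, grid.K), int)
    for (j, k), (nn, yy) in entries.items():
        n[j - 1, k - 1], y[j - 1, k - 1] = nn, yy
    return ToxCounts(n=n, yT=y)


class TestToxProb:
    def test_a_zero_returns_skeleton(self, setup53):
        ls, skel, o = setup53
        for d in ls.A:
            assert tox_prob(skel, o, d, 0.0) == skel[o.rank(d)]

    def test_closed_form_power(self):
        sk = generate_skeleton(0.3, 5, 4, 0.05)
        ls = local_set(DoseGrid(rawA=(1, 2, 3, 4, 5), rawB=(1, 2, 3)), (3, 2))
        o = enumerate_orderings(ls)[0]
        d = next(d for d in ls.A if o.rank(d) == 4)  # skeleton value 0.30
        assert tox_prob(sk, o, d, math.log(2)) == pytest.approx(0.09)

    def test_increasing_in_rank(self, setup53):
        ls, skel, o = setup53
        by_rank = sorted(ls.A, key=o.rank)
        probs = [tox_prob(skel, o, d, 0.7) for d in by_rank]
        assert all(b > a for a, b in zip(probs, probs[1:]))


class TestOrderingPosterior:
    def test_no_data_marginal_is_one(self, grid53, setup53):
        ls, skel, o = setup53
        counts = counts_on(grid53, {})
        marginal, means = ordering_posterior(counts, ls, skel, o)
        assert marginal == pytest.approx(1.0, rel=1e-9)
        _, oracle_means = trapezoid_oracle(counts, ls, skel, o, 2.0)
        for d in ls.A:
            assert means[d] == pytest.approx(oracle_means[d], rel=1e-6)

    def test_all_tox_raises_posterior_mean(self, grid53, setup53):
        ls, skel, o = setup53
        cur = ls.current
        _, prior_means = ordering_posterior(counts_on(grid53, {}), ls, skel, o)
        _, post_means = ordering_posterior(
            counts_on(grid53, {cur: (3, 3)}), ls, skel, o)
        assert post_means[cur] > prior_means[cur]

    def test_matches_trapezoid_oracle_on_random_counts(self, grid53, rng):
        for _ in range(25):
            cur = (int(rng.integers(1, 6)), int(rng.integers(1, 4)))
            ls = local_set(grid53, cur)
            skel = generate_skeleton(0.3, len(ls.A), len(ls.A) - 1, 0.05)
            entries = {}
            for d in ls.A:
                n = int(rng.integers(0, 13))
                entries[d] = (n, int(rng.integers(0, n + 1)))
            counts = counts_on(grid53, entries)
            for o in enumerate_orderings(ls):
                m, means = ordering_posterior(counts, ls, skel, o)
                m0, means0 = trapezoid_oracle(counts, ls, skel, o, 2.0)
                assert m == pytest.approx(m0, rel=1e-6)
                for d in ls.A:
                    assert means[d] == pytest.approx(means0[d], rel=1e-6)


class TestBMA:
    def test_no_data_equal_weights(self, grid53):
        ls = local_set(grid53, (3, 2))
        post = bma_estimates(counts_on(grid53, {}), ls)
        assert np.allclose(post.weights, 0.25)

    def test_single_ordering_weight_one(self, grid53):
        ls = local_set(grid53, (1, 3))  # certain ordering corner
        post = bma_estimates(counts_on(grid53, {(1, 3): (6, 2)}), ls)
        assert post.weights.shape == (1,)
        assert post.weights[0] == pytest.approx(1.0)

    @given(st.integers(0, 2**31 - 1))
    def test_weights_sum_to_one_and_pbar_bracketed(self, seed):
        rng = np.random.default_rng(seed)
        grid = DoseGrid(rawA=(1, 2, 3, 4, 5), rawB=(1, 2, 3))
        cur = (int(rng.integers(1, 6)), int(rng.integers(1, 4)))
        ls = local_set(grid, cur)
        entries = {d: (int(n := rng.integers(0, 10)), int(rng.integers(0, n + 1)))
                   for d in ls.A}
        post = bma_estimates(counts_on(grid, entries), ls)
        assert post.weights.sum() == pytest.approx(1.0)
        assert (post.weights >= 0).all()
        for d in ls.A:
            per = [means[d] for means in post.per_ordering]
            assert min(per) - 1e-12 <= post.pbar[d] <= max(per) + 1e-12

    def test_weight_concentrates_on_generating_ordering(self, grid53):
        """Scaling counts that match one ordering's skeleton drives its weight
        to 1 (posterior consistency of the model averaging)."""
        ls = local_set(grid53, (3, 2))
        skel = generate_skeleton(0.3, 5, 4, 0.05)
        target_o = enumerate_orderings(ls)[0]
        weights = []
        for m in (1, 10, 100):
            entries = {d: (10 * m, round(skel[target_o.rank(d)] * 10 * m))
                       for d in ls.A}
            post = bma_estimates(counts_on(grid53, entries), ls)
            idx = [i for i, o in enumerate(post.orderings)
                   if o.ranks == target_o.ranks][0]
            weights.append(post.weights[idx])
        assert weights[0] < weights[1] < weights[2]
        assert weights[2] > 0.9


class TestSafetyEliminate:
    def test_beta_tail_closed_forms(self, grid53):
        # 3/3 DLTs: Pr(p > 0.3 | Beta(4,1)) = 1 - 0.3^4 = 0.9919 -> eliminate
        counts = counts_on(grid53, {(2, 2): (3, 3)})
        out = safety_eliminate(counts, target=0.3, cutoff=0.95)
        assert (2, 2) in out
        # 0/3 DLTs: Pr(p > 0.3 | Beta(1,4)) = 0.7^4 = 0.2401 -> keep
        counts = counts_on(grid53, {(2, 2): (3, 0)})
        assert safety_eliminate(counts, 0.3, 0.95) == set()

    def test_upward_closure(self, grid53):
        counts = counts_on(grid53, {(2, 2): (3, 3)})
        out = safety_eliminate(counts, 0.3, 0.95)
        assert out == {(j, k) for j in range(2, 6) for k in range(2, 4)}

    def test_min_n_gate(self, grid53):
        counts = counts_on(grid53, {(2, 2): (2, 2)})
        assert safety_eliminate(counts, 0.3, 0.95, min_n=3) == set()
        assert (2, 2) in safety_eliminate(counts, 0.3, 0.95, min_n=1)

    @given(st.integers(0, 2**31 - 1), st.sampled_from([0.85, 0.90, 0.95]))
    def test_monotone_in_cutoff_and_upward_closed(self, seed, ct):
        rng = np.random.default_rng(seed)
        n = rng.integers(0, 10, (5, 3))
        y = np.array([[rng.integers(0, nn + 1) for nn in row] for row in n])
        counts = ToxCounts(n=n, yT=y)
        strict = safety_eliminate(counts, 0.3, ct)
        loose = safety_eliminate(counts, 0.3, 0.99)
        assert loose <= strict
        for (j, k) in strict:
            assert all((jj, kk) in strict
                       for jj in range(j, 6) for kk in range(k, 4))
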