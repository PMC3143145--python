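"""Linkage-disequilibrium screening and the site-exclusion rule."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_haploid
from mitonuc.ld import LDPair, exclude_linked_sites, pairwise_ld
from mitonuc.seqdata import GapMode


def fisher_two_tailed_enumeration(table):
    """Independent oracle: enumerate all 2x2 tables with the observed
    margins and sum hypergeometric probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestPairwiseLD:
    def test_perfect_cosegregation(self):
        seqs = ["AA" + "C" * 4] * 5 + ["TT" + "C" * 4] * 5
        pairs = pairwise_ld(make_haploid(seqs))
        assert len(pairs) == 1
        assert pairs[0].r_ld == pytest.approx(1.0)
        assert pairs[0].significant

    def test_independent_sites_r_zero(self):
        # 2x2 balanced: counts 5,5 x 5,5 evenly distributed
        seqs = (["AA"] * 3 + ["AT"] * 3 + ["TA"] * 3 + ["TT"] * 3)
        seqs = [s + "CCCC" for s in seqs]
        pairs = pairwise_ld(make_haploid(seqs))
        assert pairs[0].r_ld == pytest.approx(0.0, abs=1e-12)

    def test_fisher_p_for_5_0_0_5_table(self):
        seqs = ["AA" + "G" * 6] * 5 + ["TT" + "G" * 6] * 5
        p = pairwise_ld(make_haploid(seqs))[0].p_value
        # 2 / C(10,5)
        assert p == pytest.approx(2 / 252, rel=1e-9)

    def test_fisher_matches_enumeration_oracle(self, rng):
        for _ in range(60):
            n = int(rng.integers(6, 31))
            a_ind = rng.random(n) < rng.uniform(0.2, 0.8)
            b_ind = rng.random(n) < rng.uniform(0.2, 0.8)
            if a_ind.all() or (~a_ind).all() or b_ind.all() or (~b_ind).all():
                continue
            seqs = [
                ("A" if x else "T") + ("C" if y else "G") + "AAAA"
                for x, y in zip(a_ind, b_ind)
            ]
            p = pairwise_ld(make_haploid(seqs))[0].p_value
            table = [
                [int((a_ind & b_ind).sum()), int((a_ind & ~b_ind).sum())],
                [int((~a_ind & b_ind).sum()), int((~a_ind & ~b_ind).sum())],
            ]
            assert p == pytest.approx(fisher_two_tailed_enumeration(table), abs=1e-10)

    def test_fewer_than_two_polymorphic_sites_gives_empty(self):
        assert pairwise_ld(make_haploid(["AAAA", "AAAT"])) == []


class TestExcludeLinkedSites:
    def test_no_significant_pairs(self):
        pairs = [LDPair(1, 5, 0.9, 0.5, False)]
        res = exclude_linked_sites(pairs)
        assert res.excluded_sites == frozenset()
        assert res.retained_sites == {1, 5}

    def test_both_members_of_flagged_pair_excluded(self):
        pairs = [LDPair(3, 9, 0.9, 0.001, True), LDPair(3, 12, 0.2, 0.001, True)]
        res = exclude_linked_sites(pairs, threshold_r=0.5)
        assert res.excluded_sites == {3, 9}
        assert res.retained_sites == {12}

    def test_planted_fully_linked_block_all_excluded(self, rng):
        """Five perfectly co-segregating sites plus unlinked noise sites; a
        brute-force pair scan of the planted block is the oracle."""
        n = 24
        block = rng.random(n) < 0.5
        cols = []
        for _ in range(5):
            cols.append(["A" if x else "T" for x in block])
        for _ in range(6):
            noise = rng.random(n) < 0.5
            cols.append(["C" if x else "G" for x in noise])
        seqs = ["".join(col[i] for col in cols) for i in range(n)]
        pairs = pairwise_ld(make_haploid(seqs))
        res = exclude_linked_sites(pairs)
        assert {1, 2, 3, 4, 5} <= res.excluded_sites

    def test_exclusion_monotone_in_threshold(self, rng):
        seqs = ["".join(rng.choice(list("AT"), 8)) for _ in range(20)]
        pairs = pairwise_ld(make_haploid(seqs))
        prev = None
        for thr in (0.9, 0.7, 0.5, 0.3, 0.1):
            res = exclude_linked_sites(pairs, threshold_r=thr)
            if prev is not None:
                assert prev <= res.excluded_sites
            prev = res.excluded_sites

    def test_false_positive_rate_on_unlinked_sites(self, rng):
        """Free recombination between sites: the joint rule (P<0.05 and
        r>0.5) excludes under 10% of sites on average over 100 replicates.
        At study-scale sample sizes the r>0.5 arm is the binding constraint
        (|r|>0.5 under independence is vanishingly rare for n of dozens)."""
        fracs = []
        for _ in range(100):
            n = 60
            cols = []
            for _ in range(8):
                p = rng.uniform(0.2, 0.8)
                col = rng.random(n) < p
                if col.all() or (~col).all():
                    col[0] = ~col[0]
                cols.append(["A" if x else "T" for x in col])
            seqs = ["".join(c[i] for c in cols) for i in range(n)]
            pairs = pairwise_ld(make_haploid(seqs))
            res = exclude_linked_sites(pairs)
            total = len(res.excluded_sites) + len(res.retained_sites)
            fracs.append(len(res.excluded_sites) / total)
        assert np.mean(fracs) < 0.10


class TestCompareClusterings:
    def _mk(self, Q, k):
        from mitonuc.clustering import ClusterRun, KSelection

        inds = tuple(f"i{j}" for j in range(Q.shape[0]))
        run = ClusterRun(K=Q.shape[1], Q=Q, P=np.zeros((Q.shape[1], 1, 2)),
                         alpha=0.1, lnPD=-1.0, seed=0, mcmc=(1, 2),
                         individuals=inds)
        sel = KSelection((1, 2, 3, 4), 3, {}, {}, {}, k, True, "", {})
        return sel, run

    def test_identical_q_full_agreement(self, rng):
        Q = rng.dirichlet([1, 1, 1], size=12)
        from mitonuc.ld import compare_clusterings

        rep = compare_clusterings(self._mk(Q, 3), self._mk(Q.copy(), 3))
        assert rep.agreement == 1.0 and rep.same_k
        assert rep.changed_individuals == ()

    def test_column_permutation_invariance(self, rng):
        from mitonuc.ld import compare_clusterings

        Q = rng.dirichlet([1, 1, 1], size=30)
        perm = Q[:, [2, 0, 1]]
        rep = compare_clusterings(self._mk(Q, 3), self._mk(perm, 3))
        assert rep.agreement == 1.0

    def test_different_individual_sets_rejected(self, rng):
        from mitonuc.clustering import ClusteringError
        from mitonuc.ld import compare_clusterings

        Q = rng.dirichlet([1, 1], size=6)
        sel_a, run_a = self._mk(Q, 2)
        sel_b, run_b = self._mk(Q[:5], 2)
        with pytest.raises(ClusteringError, match="different individuals"):
            compare_clusterings((sel_a, run_a), (sel_b, run_b))

    def test_random_q_agreement_matches_exhaustive_permutation_oracle(self, rng):
        from mitonuc.ld import compare_clusterings

        Qa = rng.dirichlet([1, 1, 1], size=60)
        Qb = rng.dirichlet([1, 1, 1], size=60)
        rep = compare_clusterings(self._mk(Qa, 3), self._mk(Qb, 3))
        a, b = Qa.argmax(axis=1), Qb.argmax(axis=1)
        best = max(
            np.mean(a == np.asarray(p)[b])
            for p in itertools.permutations(range(3))
        )
        assert rep.agreement == pytest.approx(best)
        assert 0.25 < rep.agreement < 0.55  # near 1/3 for independent labels
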