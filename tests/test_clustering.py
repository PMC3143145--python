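"""Admixture-model Gibbs sampler, deltaK model choice, hierarchy, flags."""

import itertools
import math

import numpy as np
import pytest

from conftest import make_diploid, make_haploid
from mitonuc import simulate as sm
from mitonuc.clustering import (
    ClusterRun,
    ClusteringError,
    build_genotype_matrix,
    evanno_delta_k,
    flag_intercluster_heterozygotes,
    hierarchical_analysis,
    match_labels,
    run_admixture,
    select_k,
)
from mitonuc.seqdata import GapMode, encode_indel_series


def _mk_run(Q):
    inds = tuple(f"i{j}" for j in range(Q.shape[0]))
    return ClusterRun(K=Q.shape[1], Q=np.asarray(Q, dtype=float),
                      P=np.zeros((Q.shape[1], 1, 2)), alpha=0.1, lnPD=-1.0,
                      seed=0, mcmc=(1, 2), individuals=inds)


class TestGenotypeMatrix:
    def test_haploid_site_loci(self):
        seqs = ["AAAT", "AAAA", "ATAA", "AAAA", "ATAT"]
        gm = build_genotype_matrix(mito=make_haploid(seqs))
        assert gm.n_loci == 2  # columns 2 and 4 polymorphic
        assert all(p == 1 for p in gm.ploidy)
        assert gm.provenance == "mito_sites"

    def test_site_filter_drops_loci(self):
        from mitonuc.ld import SiteFilterResult

        seqs = ["AAAT", "AAAA", "ATAA", "AAAA", "ATAT"]
        filt = SiteFilterResult(frozenset({2}), frozenset({4}), 0.5, 0.05, 1)
        gm = build_genotype_matrix(mito=make_haploid(seqs), mito_filter=filt)
        assert gm.n_loci == 1
        assert gm.loci == ("mito_4",)

    def test_combined_counts_mito_plus_nuclear_plus_indels(self, two_pop_data):
        _, mito, nuc, _ = two_pop_data
        gm_m = build_genotype_matrix(mito=mito)
        gm_n = build_genotype_matrix(nuclear=nuc)
        gm_c = build_genotype_matrix(mito=mito, nuclear=nuc)
        assert gm_c.n_loci == gm_m.n_loci + gm_n.n_loci
        intervals = [(10, 14), (30, 37)]
        indels = encode_indel_series(nuc, intervals)
        gm_ci = build_genotype_matrix(mito=mito, nuclear=nuc, indels=indels)
        n_poly = sum(1 for s in indels.series if s[0] not in indels.monomorphic)
        assert gm_ci.n_loci == gm_c.n_loci + n_poly

    def test_disjoint_individual_sets_rejected(self):
        m = make_haploid(["AAT", "AAA"])
        nuc = make_diploid([("CCT", "CCC")])
        nuc2 = type(nuc)(
            locus_name=nuc.locus_name, ploidy=nuc.ploidy,
            alignment_length=3,
            sequences=(("zz", 0, "CCT"), ("zz", 1, "CCC")),
            samples=(type(nuc.samples[0])("zz", "ISOX", "wild"),),
        )
        with pytest.raises(ClusteringError, match="disjoint"):
            build_genotype_matrix(mito=m, nuclear=nuc2)


class TestRunAdmixture:
    def test_k1_forces_unit_ancestry(self, two_pop_data):
        _, _, nuc, _ = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc)
        run = run_admixture(gm, K=1, burn_in=20, reps=60, seed=0)
        assert np.all(run.Q == 1.0)

    def test_two_population_assignment_recovery(self, two_pop_data):
        _, _, nuc, truth = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc, gap_mode=GapMode.fifth_state)
        run = run_admixture(gm, K=2, burn_in=300, reps=1000, seed=1)
        tmap = truth.by_id()
        demes = [tmap[i].deme for i in run.individuals]
        maj = run.majority()
        # after label matching, >=95% of individuals strongly assigned home
        best = 0
        for perm in itertools.permutations(range(2)):
            lab = {d: k for d, k in zip(sorted(set(demes)), perm)}
            ok = np.mean([
                run.Q[i, lab[d]] > 0.9 for i, d in enumerate(demes)
            ])
            best = max(best, ok)
        assert best >= 0.95

    def test_engines_agree_on_fixture(self, two_pop_data):
        _, _, nuc, _ = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc)
        a = run_admixture(gm, K=2, burn_in=500, reps=3000, seed=3, engine="numba")
        b = run_admixture(gm, K=2, burn_in=500, reps=3000, seed=3, engine="numpy")
        perm = match_labels(a.Q, b.Q)
        aligned = np.empty_like(b.Q)
        aligned[:, perm] = b.Q
        assert np.abs(a.Q - aligned).max() < 0.15
        assert a.lnPD == pytest.approx(b.lnPD, abs=8.0)

    def test_posterior_matches_exhaustive_enumeration_on_toy(self):
        """2 diploid individuals, 1 biallelic locus, K=2, alpha fixed:
        posterior mean ancestry equals exact enumeration over the 16 copy
        assignments (Dirichlet-multinomial marginals)."""
        pairs = [("A", "T"), ("A", "A")]
        ds = make_diploid([(a, b) for a, b in pairs])
        gm = build_genotype_matrix(nuclear=ds)
        K, lam, alpha = 2, 1.0, 1.0
        copies = [(0, 0), (0, 1), (1, 0), (1, 1)]  # (ind, allele code) flat
        obs_ind = np.array([0, 0, 1, 1])
        obs_allele = np.array([0, 1, 0, 0])

        def dm_weight(counts, conc, dim):
            tot = sum(counts)
            num = math.lgamma(dim * conc) - math.lgamma(dim * conc + tot)
            num += sum(math.lgamma(conc + c) - math.lgamma(conc) for c in counts)
            return num

        post = np.zeros((2, K))
        total = 0.0
        weights = []
        zs = list(itertools.product(range(K), repeat=4))
        for z in zs:
            lw = 0.0
            for k in range(K):
                ac = [0, 0]
                for m in range(4):
                    if z[m] == k:
                        ac[obs_allele[m]] += 1
                lw += dm_weight(ac, lam, 2)
            for i in range(2):
                qc = [0, 0]
                for m in range(4):
                    if obs_ind[m] == i:
                        qc[z[m]] += 1
                lw += dm_weight(qc, alpha, K)
            weights.append(math.exp(lw))
        weights = np.asarray(weights)
        weights /= weights.sum()
        for w, z in zip(weights, zs):
            for i in range(2):
                qc = np.zeros(K)
                for m in range(4):
                    if obs_ind[m] == i:
                        qc[z[m]] += 1
                post[i] += w * (alpha + qc) / (K * alpha + 2)
        run = run_admixture(gm, K=2, burn_in=2000, reps=60000, seed=11,
                            alpha_init=alpha, alpha_sd=0.0, init="random")
        # the exact posterior is symmetric in cluster labels: both rows 0.5
        assert post == pytest.approx(np.full((2, 2), 0.5), abs=1e-12)
        assert run.Q == pytest.approx(post, abs=0.02)

    def test_longer_chains_reduce_lnpd_scatter(self, two_pop_data):
        _, _, nuc, _ = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc)
        short = [run_admixture(gm, 2, 100, 300, seed=40 + r).lnPD for r in range(4)]
        long = [run_admixture(gm, 2, 1000, 8000, seed=40 + r).lnPD for r in range(4)]
        assert np.std(long) < np.std(short) * 1.2

    def test_no_admixture_model_gives_hard_assignments(self, two_pop_data):
        _, _, nuc, truth = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc, gap_mode=GapMode.fifth_state)
        run = run_admixture(gm, K=2, burn_in=200, reps=700, seed=2,
                            model="no_admixture")
        # posterior means of one-origin indicators stay near 0/1 here
        assert (run.Q.max(axis=1) > 0.95).mean() >= 0.9
        tmap = truth.by_id()
        demes = [tmap[i].deme for i in run.individuals]
        maj = run.majority()
        groups = {d: set(maj[i] for i, dd in enumerate(demes) if dd == d)
                  for d in set(demes)}
        assert groups["A"] != groups["B"]

    def test_input_validation(self, two_pop_data):
        _, _, nuc, _ = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc)
        with pytest.raises(ClusteringError):
            run_admixture(gm, K=0, burn_in=10, reps=20)
        with pytest.raises(ClusteringError):
            run_admixture(gm, K=200, burn_in=10, reps=20)
        with pytest.raises(ClusteringError):
            run_admixture(gm, K=2, burn_in=20, reps=10)


class TestSelectK:
    def test_delta_k_closed_form(self):
        means = {1: -100.0, 2: -50.0, 3: -48.0, 4: -47.0}
        sds = {1: 1.0, 2: 2.0, 3: 1.0, 4: 1.0}
        dk = evanno_delta_k(means, sds)
        assert dk[2] == pytest.approx(24.0)
        assert dk[3] == pytest.approx(1.0)

    def test_zero_sd_gives_nan(self):
        dk = evanno_delta_k({1: -10.0, 2: -5.0, 3: -4.0, 4: -3.9},
                            {1: 1.0, 2: 0.0, 3: 1.0, 4: 1.0})
        assert np.isnan(dk[2])

    def test_requires_four_ks_and_three_replicates(self, two_pop_data):
        _, _, nuc, _ = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc)
        with pytest.raises(ClusteringError):
            select_k(gm, (1, 2, 3), replicates=3)
        with pytest.raises(ClusteringError):
            select_k(gm, (1, 2, 3, 4), replicates=2)

    def test_monomorphic_matrix_chooses_k1(self):
        ds = make_haploid(["AAAA"] * 8)
        gm = build_genotype_matrix(mito=ds)
        sel = select_k(gm, (1, 2, 3, 4), replicates=3, burn_in=10, reps=30)
        assert sel.chosen_K == 1
        assert "no polymorphic" in sel.note

    def test_two_population_k_recovery(self, two_pop_data):
        _, _, nuc, _ = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc, gap_mode=GapMode.fifth_state)
        sel = select_k(gm, (1, 2, 3, 4), replicates=3, burn_in=250, reps=900,
                       seed=5)
        assert sel.chosen_K == 2 and sel.reliable

    def test_panmictic_population_flagged_unreliable(self):
        """Null simulation: a panmictic population with free recombination
        among sites (iid Hardy-Weinberg genotypes, the model's own null).
        No dominant deltaK peak should survive, or no individuals should be
        confidently assigned.  (A single non-recombining fragment is NOT a
        valid null here: its deepest coalescent split genuinely mimics
        two-lineage structure.)"""
        from mitonuc.clustering import GenotypeMatrix

        hits = 0
        for r in range(6):
            rng = np.random.default_rng(950 + r)
            n, L = 24, 40
            p = rng.uniform(0.1, 0.9, L)
            alleles = (rng.random((n, L, 2)) < p[None, :, None]).astype(int)
            gm = GenotypeMatrix(
                individuals=tuple(f"i{k}" for k in range(n)),
                isolates=("ISO1",) * n,
                loci=tuple(f"l{j}" for j in range(L)),
                ploidy=(2,) * L, n_states=(2,) * L,
                alleles=alleles, provenance="nuc_sites",
            )
            sel = select_k(gm, (1, 2, 3, 4), replicates=4, burn_in=250,
                           reps=900, seed=950 + r)
            hits += not sel.reliable
        assert hits >= 4


class TestHierarchy:
    def test_nested_two_by_two_structure_recovered(self):
        """Four demes in two super-groups: two-level tree 2 -> (2, 2)."""
        demes = tuple(sm.Deme(x, 60, 60) for x in ("anc", "AB", "A", "B", "C", "D"))
        events = (
            sm.Split(4000.0, "AB", "A"), sm.Split(4001.0, "AB", "B"),
            sm.Split(4002.0, "anc", "C"), sm.Split(4003.0, "anc", "D"),
            sm.Split(20000.0, "anc", "AB"),
        )
        sc = sm.SimScenario(
            name="nested", inheritance="haplodiploid", demes=demes,
            events=events, nuc_mu=2e-6,
            sampling=tuple(sm.SampleSpec(d, 12, f"ISO_{d}") for d in "ABCD"),
            seed=3,
        )
        _, nuc, truth = sm.simulate(sc)
        gm = build_genotype_matrix(nuclear=nuc, gap_mode=GapMode.fifth_state)
        res = hierarchical_analysis(
            gm, (1, 2, 3, 4), threshold=0.6, min_n=12, max_depth=2,
            replicates=3, burn_in=250, reps=900, seed=2,
        )
        assert res.root.selection.chosen_K == 2
        assert len(res.root.children) == 2
        child_ks = sorted(c.selection.chosen_K for c in res.root.children
                          if c.selection is not None)
        assert child_ks == [2, 2]
        # each leaf subset should be (close to) a true deme pair then deme
        tmap = truth.by_id()
        for child in res.root.children:
            demes_here = {tmap[i].deme for i in child.individuals}
            assert demes_here in ({"A", "B"}, {"C", "D"})

    def test_monomorphic_top_level_single_node(self):
        ds = make_haploid(["AAAA"] * 12)
        gm = build_genotype_matrix(mito=ds)
        res = hierarchical_analysis(gm, (1, 2, 3, 4), replicates=3,
                                    burn_in=10, reps=30)
        assert res.root.children == ()

    def test_homogeneous_isolates_rule_matches_direct_means(self, two_pop_data):
        _, _, nuc, truth = two_pop_data
        gm = build_genotype_matrix(nuclear=nuc, gap_mode=GapMode.fifth_state)
        res = hierarchical_analysis(
            gm, (1, 2, 3, 4), subset_rule="homogeneous_isolates",
            homogeneity=0.9, min_n=10, max_depth=1, replicates=3,
            burn_in=250, reps=900, seed=4,
        )
        run = res.root.run
        qmax = run.Q.max(axis=1)
        iso_mean = {}
        for i, iso in enumerate(gm.isolates):
            iso_mean.setdefault(iso, []).append(qmax[i])
        grouped = {iso for iso, v in iso_mean.items() if np.mean(v) >= 0.9}
        in_children = {i for c in res.root.children for i in c.individuals}
        expect = {
            ind for ind, iso in zip(gm.individuals, gm.isolates) if iso in grouped
        }
        assert in_children == expect


class TestHeterozygoteFlags:
    def test_band_rule(self):
        run = _mk_run(np.array([[0.5, 0.5, 0.0], [0.9, 0.1, 0.0],
                                [0.41, 0.59, 0.0], [0.3, 0.3, 0.4]]))
        flags = flag_intercluster_heterozygotes(run)
        flagged = {f[0]: f[1] for f in flags}
        assert set(flagged) == {"i0", "i2"}
        assert flagged["i0"] == (0, 1)

    def test_planted_f1_detection_rate(self):
        """Structured F1 hybrids are flagged by the 0.405-0.595 band in >=90%
        of cases over 20 replicates."""
        flagged = total = 0
        for r in range(20):
            sc = sm.two_population_scenario(split_time=4000, n_per_pop=12,
                                            n_f1=6, seed=600 + r)
            _, nuc, truth = sm.simulate(sc)
            gm = build_genotype_matrix(nuclear=nuc, gap_mode=GapMode.fifth_state)
            run = run_admixture(gm, K=2, burn_in=300, reps=1000, seed=600 + r)
            f1s = {t.individual_id for t in truth.individuals
                   if t.hybrid_class == "F1"}
            hits = {f[0] for f in flag_intercluster_heterozygotes(run)}
            flagged += len(f1s & hits)
            total += len(f1s)
        assert flagged / total >= 0.9
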