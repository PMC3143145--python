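"""AMOVA, pairwise Phi_ST and F_IS against brute-force oracles."""

import numpy as np
import pytest

from conftest import make_diploid, make_haploid
from mitonuc import simulate as sm
from mitonuc.fstats import (
    _nested_components,
    amova,
    distance_matrix,
    fis,
    pairwise_fst,
    pairwise_fst_from_distances,
)
from mitonuc.seqdata import GapMode


# ---------------------------------------------------------------------------
# independent oracle: literal translation of the nested ANOVA definitions,
# built from explicit group loops (no shared code with the implementation)
# ---------------------------------------------------------------------------

def brute_force_components(D, levels):
    N = D.shape[0]

    def ss(idx):
        tot = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                tot += D[idx[a], idx[b]]
        return tot / len(idx) if idx else 0.0

    def units(lab):
        out = []
        for u in sorted(set(lab)):
            out.append([i for i in range(N) if lab[i] == u])
        return out

    k = len(levels)
    SS, df = [], []
    prev_units = [list(range(N))]
    for lab in levels:
        us = units(lab)
        SS.append(sum(ss(u) for u in prev_units) - sum(ss(u) for u in us))
        df.append(len(us) - len(prev_units))
        prev_units = us
    SS.append(sum(ss(u) for u in prev_units))
    df.append(N - len(prev_units))
    MS = [s / d if d > 0 else 0.0 for s, d in zip(SS, df)]

    def A(level, m):
        if level == -1:
            return sum(len(u) ** 2 for u in units(levels[m])) / N
        tot = 0.0
        for u in units(levels[level]):
            sub = [levels[m][i] for i in u]
            for v in sorted(set(sub)):
                tot += sub.count(v) ** 2 / len(u)
        return tot

    sigma = [0.0] * (k + 1)
    sigma[k] = MS[k]
    for j in range(k - 1, -1, -1):
        if df[j] <= 0:
            continue
        acc = MS[j] - sigma[k]
        for m in range(j + 1, k):
            cjm = (A(j, m) - A(j - 1, m)) / df[j]
            acc -= cjm * sigma[m]
        cjj = (A(j, j) - A(j - 1, j)) / df[j]
        sigma[j] = acc / cjj
    return np.array(sigma)


def random_dataset(rng, n_iso=4, per_iso=5, L=30, diploid=True):
    isolates = []
    pairs = []
    for g in range(n_iso):
        base = rng.choice(list("ACGT"), L)
        for _ in range(per_iso):
            def mutate():
                s = base.copy()
                for j in rng.choice(L, rng.integers(1, 5), replace=False):
                    s[j] = rng.choice(list("ACGT"))
                return "".join(s)
            if diploid:
                pairs.append((mutate(), mutate()))
            else:
                pairs.append((mutate(),))
            isolates.append(f"ISO{g}")
    if diploid:
        return make_diploid(pairs, isolates)
    return make_haploid([p[0] for p in pairs], isolates)


class TestComponentsOracle:
    @pytest.mark.parametrize("k_levels", [1, 2, 3])
    def test_matches_brute_force(self, rng, k_levels):
        for _ in range(5):
            n = 24
            seqs = ["".join(rng.choice(list("ACGT"), 12)) for _ in range(n)]
            D = distance_matrix(seqs)
            levels = []
            if k_levels >= 3:
                levels.append(np.repeat([0, 1], 12))
            if k_levels >= 2:
                levels.append(np.repeat([0, 1, 2, 3], 6))
            levels.append(np.repeat(np.arange(n // 2), 2))
            _, _, got = _nested_components(D, levels)
            expected = brute_force_components(D, levels)
            assert got == pytest.approx(expected, abs=1e-10)


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self):
        seqs = ["A" * 10] * 5 + [("A" * 5 + "T" * 5)] * 5
        D = distance_matrix(seqs)
        res = pairwise_fst_from_distances(D, np.array([0] * 5 + [1] * 5),
                                          n_perm=20, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.p_value < 0.05

    def test_self_comparison_zero_and_symmetry(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), 15)) for _ in range(12)]
        D = distance_matrix(seqs)
        pop = np.array([0] * 6 + [1] * 6)
        a = pairwise_fst_from_distances(D, pop, n_perm=10, seed=1)
        b = pairwise_fst_from_distances(D, 1 - pop, n_perm=10, seed=1)
        assert a.phi_st == pytest.approx(b.phi_st, abs=1e-12)
        same = ["ACGTACGT"] * 4 + ["ACGAACGT"] * 4
        D2 = distance_matrix(same)
        pops = np.array([0, 1] * 4)  # identical composition in both units
        r = pairwise_fst_from_distances(D2, pops, n_perm=10, seed=2)
        assert abs(r.phi_st) < 0.35  # near zero, small-sample noise allowed

    def test_split_time_expectation(self):
        """Two demes split tau generations ago: Slatkin's F_ST is
        (T_between - T_within) / T_between = tau / (tau + N_f) for the
        mitochondrial locus with equal deme and ancestor sizes (within-deme
        pair coalescence keeps rate 1/N_f throughout).  The ratio of summed
        variance components over 100 replicates (the consistent combined
        estimator) must sit within 3 bootstrap SEs of the theory value."""
        tau, N = 100.0, 200
        comps = []
        for r in range(100):
            sc = sm.SimScenario(
                name="split", inheritance="haplodiploid",
                demes=(sm.Deme("anc", N, N), sm.Deme("A", N, N),
                       sm.Deme("B", N, N)),
                events=(sm.Split(tau, "anc", "A"), sm.Split(tau + 1, "anc", "B")),
                sampling=(sm.SampleSpec("A", 12, "IA"),
                          sm.SampleSpec("B", 12, "IB")),
                mito_mu=5e-6, seed=4000 + r,
            )
            mito, _, _ = sm.simulate(sc)
            seqs = [s for _, _, s in mito.sequences]
            D = distance_matrix(seqs)
            _, _, sigma = _nested_components(
                D, [np.array([0] * 12 + [1] * 12)]
            )
            comps.append(sigma)
        comps = np.asarray(comps)
        expected = tau / (tau + N)
        combined = comps[:, 0].sum() / comps.sum()
        rng = np.random.default_rng(0)
        boots = []
        for _ in range(300):
            idx = rng.integers(0, len(comps), len(comps))
            boots.append(comps[idx, 0].sum() / comps[idx].sum())
        se = np.std(boots, ddof=1)
        assert abs(combined - expected) < 3 * se

    def test_amova_two_units_equals_pairwise_fst(self, rng):
        ds = random_dataset(rng, n_iso=2, per_iso=6, diploid=False)
        res_fst = pairwise_fst(ds, "ISO0", "ISO1", n_perm=1, seed=0)
        res_amova = amova(ds, None, n_perm=0)
        assert res_amova.phi["Phi_ST"] == pytest.approx(res_fst.phi_st, abs=1e-10)


class TestAmova:
    def test_all_identical_sequences_zero_components(self):
        ds = make_haploid(["ACGT" * 3] * 8, ["I1"] * 4 + ["I2"] * 4)
        res = amova(ds, None, n_perm=0)
        assert all(v == 0 for v in res.variance_components)

    def test_two_fixed_groups_hundred_percent_among(self):
        ds = make_haploid(["AAAA"] * 4 + ["TTTT"] * 4,
                          ["I1"] * 4 + ["I2"] * 4)
        res = amova(ds, None, n_perm=0)
        assert res.percentages[0] == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self, rng):
        ds = random_dataset(rng)
        grouping = {"ISO0": "g1", "ISO1": "g1", "ISO2": "g2", "ISO3": "g2"}
        res = amova(ds, grouping, n_perm=0)
        assert sum(res.percentages) == pytest.approx(100.0, abs=0.01)
        assert len(res.level_names) == 4  # groups/isolates/individuals/within

    def test_singleton_group_level_omitted(self, rng):
        ds = random_dataset(rng, n_iso=2)
        res = amova(ds, {"ISO0": "g", "ISO1": "g"}, n_perm=0)
        assert "among_groups" not in res.level_names
        assert any("single group" in n for n in res.notes)

    def test_planted_variance_ratios_recovered(self, rng):
        """Three-level generative model with known between/within variance:
        two groups of isolates fixed for group haplotypes 12 steps apart,
        isolates differing by 2 private sites, individuals mutation-free.
        Expected percentages follow from the planted distances."""
        recovered = []
        for rep in range(50):
            L = 60
            g_seqs = []
            base = rng.choice(list("ACGT"), L)
            other = base.copy()
            for j in rng.choice(L, 12, replace=False):
                other[j] = "T" if other[j] != "T" else "A"
            seqs, isolates = [], []
            for g, groot in enumerate((base, other)):
                for iso in range(2):
                    iso_seq = groot.copy()
                    for j in rng.choice(L, 2, replace=False):
                        iso_seq[j] = rng.choice(list("ACGT"))
                    for _ in range(5):
                        seqs.append("".join(iso_seq))
                        isolates.append(f"I{g}{iso}")
            ds = make_haploid(seqs, isolates)
            res = amova(ds, {f"I{g}{i}": f"g{g}" for g in range(2)
                             for i in range(2)}, n_perm=0)
            recovered.append(res.percentages)
        mean_pct = np.mean(recovered, axis=0)
        # among groups dominates; within isolates carries no variance
        assert mean_pct[0] > 60
        assert abs(mean_pct[2]) < 5


class TestFis:
    def test_complete_heterozygote_deficit(self):
        pairs = [("AAAA", "AAAA"), ("AAAA", "AAAA"),
                 ("AATT", "AATT"), ("AATT", "AATT")]
        ds = make_diploid(pairs)
        res = fis(ds, n_perm=50, seed=0)
        f, p = res["ISO1"]
        assert f == pytest.approx(1.0)

    def test_hardy_weinberg_mean_near_zero(self, rng):
        vals = []
        for _ in range(100):
            hapA, hapB = "AAAA", "AATT"
            pairs = []
            for _ in range(12):
                a = hapA if rng.random() < 0.5 else hapB
                b = hapA if rng.random() < 0.5 else hapB
                pairs.append((a, b))
            ds = make_diploid(pairs)
            f, _ = fis(ds, n_perm=1, seed=0)["ISO1"]
            if f is not None:
                vals.append(f)
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_wahlund_effect_positive_and_significant(self, rng):
        """Pooling two subunits fixed for different haplotypes: F_IS > 0
        with p < 0.05 in the majority of 50 replicates."""
        hits = 0
        for rep in range(50):
            pairs = []
            for _ in range(6):
                pairs.append(("AAAA", "AAAA"))
            for _ in range(6):
                pairs.append(("TTTT", "TTTT"))
            # a little within noise so permutations vary
            noisy = []
            for a, b in pairs:
                lst = list(a)
                if rng.random() < 0.3:
                    lst[3] = "C"
                noisy.append(("".join(lst), b))
            ds = make_diploid(noisy)
            f, p = fis(ds, n_perm=99, seed=rep)["ISO1"]
            hits += (f is not None and f > 0 and p is not None and p < 0.05)
        assert hits > 25

    def test_small_unit_returns_na(self):
        ds = make_diploid([("AAAA", "AATT")])
        f, p = fis(ds, n_perm=10, seed=0)["ISO1"]
        assert f is None and p is None


class TestPermutationUnit:
    def test_genotype_vs_allele_unit_differ_under_hwd(self, rng):
        """With strong heterozygote deficit, permuting genotypes (alleles
        travel in pairs) and permuting alleles give different null
        distributions, hence different p-values on the same data."""
        pairs_a = [("AAAA", "AAAA")] * 5 + [("ATTT", "ATTT")] * 1
        pairs_b = [("TTTT", "TTTT")] * 5 + [("TAAA", "TAAA")] * 1
        ds = make_diploid(pairs_a + pairs_b,
                          ["U1"] * 6 + ["U2"] * 6)
        g = pairwise_fst(ds, "U1", "U2", n_perm=999, seed=3, unit="genotype")
        a = pairwise_fst(ds, "U1", "U2", n_perm=999, seed=3, unit="allele")
        assert g.randomization_unit == "genotype"
        assert a.randomization_unit == "allele"
        assert g.p_value != a.p_value
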