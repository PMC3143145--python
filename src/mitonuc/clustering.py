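"""Bayesian admixture-model clustering with Evanno's deltaK model choice.

The model is the standard admixture mixture model for multilocus genotypes:
each allele copy of individual i at locus l originates from cluster k with
probability Q_ik and carries allele a with probability P_kla; Q_i has a
symmetric Dirichlet(alpha) prior and P_kl a Dirichlet(lambda=1) prior.
Inference is by Gibbs sampling -- allele-copy cluster assignments given
(Q, P); Q from Dirichlet(alpha + copy counts); P from Dirichlet(1 + allele
counts); alpha by random-walk Metropolis under a uniform prior on (0, 10].
The reported model support is the posterior-mean log probability of the data
ln P(D) estimated as mean(ll) - var(ll)/2 over retained sweeps.

Haploid (mitochondrial) loci enter as single allele copies; diploid loci as
two unordered copies, which is what lets near-0.5/0.5 ancestry rows flag
inter-cluster heterozygotes (F1-like hybrids between deeply divergent
lineages).

Model choice across K follows Evanno's deltaK -- the second-order rate of
change of ln P(D) normalized by its between-replicate standard deviation --
with the smallest K among near-equal peaks preferred and a reliability note
when no dominant peak exists.  The hierarchical protocol re-runs the model
choice within subsets defined by an assignment threshold (or by grouping
homogeneous isolates), mirroring how layered structure is peeled in
practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .seqdata import AlignedDataset, GapMode, IndelMatrix

try:  # the jitted sweep kernel is ~20x faster; numpy path kept as reference
    from ._gibbs import gibbs_admixture as _gibbs_kernel
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "GenotypeMatrix",
    "ClusterRun",
    "KSelection",
    "HierarchicalResult",
    "HierarchicalNode",
    "build_genotype_matrix",
    "run_admixture",
    "select_k",
    "evanno_delta_k",
    "hierarchical_analysis",
    "flag_intercluster_heterozygotes",
    "match_labels",
    "compare_clusterings",
]

MISSING = -9


class ClusteringError(ValueError):
    pass


@dataclass(frozen=True)
class GenotypeMatrix:
    individuals: tuple[str, ...]
    isolates: tuple[str, ...]  # parallel to individuals
    loci: tuple[str, ...]
    ploidy: tuple[int, ...]  # per locus
    n_states: tuple[int, ...]  # allele states per locus
    #: allele codes, shape (n_individuals, n_loci, 2); slot 1 is MISSING for
    #: haploid loci
    alleles: "np.ndarray"
    provenance: str = "combined"

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.individuals.index(i) for i in individual_ids]
        return GenotypeMatrix(
            individuals=tuple(self.individuals[i] for i in idx),
            isolates=tuple(self.isolates[i] for i in idx),
            loci=self.loci,
            ploidy=self.ploidy,
            n_states=self.n_states,
            alleles=self.alleles[idx],
            provenance=self.provenance,
        )


@dataclass(frozen=True)
class ClusterRun:
    K: int
    Q: "np.ndarray"  # (n_individuals, K), rows sum to 1
    P: "np.ndarray"  # (K, n_loci, max_states) posterior mean frequencies
    alpha: float
    lnPD: float
    seed: int
    mcmc: tuple[int, int]  # (burn_in, reps)
    individuals: tuple[str, ...]

    def majority(self) -> np.ndarray:
        return self.Q.argmax(axis=1)


@dataclass(frozen=True)
class KSelection:
    tested_Ks: tuple[int, ...]
    replicates: int
    lnPD_mean: dict[int, float]
    lnPD_sd: dict[int, float]
    deltaK: dict[int, float]  # interior K only; may hold nan when sd = 0
    chosen_K: int
    reliable: bool
    note: str = ""
    runs: dict[int, tuple] = field(default_factory=dict, compare=False)

    def best_run(self) -> ClusterRun:
        reps = self.runs[self.chosen_K]
        return max(reps, key=lambda r: r.lnPD)


@dataclass(frozen=True)
class HierarchicalNode:
    label: str
    individuals: tuple[str, ...]
    selection: KSelection | None
    run: ClusterRun | None
    unassigned: tuple[str, ...]
    children: tuple["HierarchicalNode", ...]
    note: str = ""


@dataclass(frozen=True)
class HierarchicalResult:
    root: HierarchicalNode
    subset_rule: str
    threshold: float

    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)


# ---------------------------------------------------------------------------
# Genotype matrix construction
# ---------------------------------------------------------------------------

def _polymorphic_codes(dataset: AlignedDataset, gap_mode: GapMode,
                       excluded_columns: set[int] | None):
    """Per polymorphic column: (original 1-based column, code array per
    allele sequence with MISSING for N, n_states)."""
    gap_mode = GapMode(gap_mode)
    mat = dataset.sequences_array()
    cols = np.arange(1, dataset.alignment_length + 1)
    if gap_mode == GapMode.ignore_gap_columns:
        keep = ~(mat == b"-").any(axis=0)
        mat = mat[:, keep]
        cols = cols[keep]
    out = []
    for j in range(mat.shape[1]):
        if excluded_columns and int(cols[j]) in excluded_columns:
            continue
        col = mat[:, j]
        states = sorted(set(col.tobytes().decode()) - {"N"})
        if gap_mode != GapMode.fifth_state and "-" in states:
            states.remove("-")
        if len(states) < 2:
            continue
        code_of = {s.encode(): c for c, s in enumerate(states)}
        codes = np.array([code_of.get(bytes(x), MISSING) for x in col])
        out.append((int(cols[j]), codes, len(states)))
    return out


def build_genotype_matrix(
    mito: AlignedDataset | None = None,
    nuclear: AlignedDataset | None = None,
    gap_mode: GapMode | str = GapMode.fifth_state,
    indels: IndelMatrix | None = None,
    mito_filter=None,
    nuclear_filter=None,
) -> GenotypeMatrix:
    """Genotype matrix over polymorphic sites (one locus per site).

    Allele states are residue states at the column (gap a state only in
    fifth_state mode, N missing).  Optional site filters drop excluded
    columns (LD-based robustness variant); ``indels`` appends binary
    presence/absence loci from the encoded intron indel series.  When both
    datasets are given, the combined matrix concatenates the haploid
    mitochondrial block and the diploid nuclear block over the shared
    individuals.
    """
    if mito is None and nuclear is None:
        raise ClusteringError("at least one dataset required")
    gap_mode = GapMode(gap_mode)
    if mito is not None and nuclear is not None:
        shared = [i for i in mito.individuals if i in set(nuclear.individuals)]
        if not shared:
            raise ClusteringError("combined matrix requested with disjoint individual sets")
        provenance = "combined"
    else:
        ds = mito or nuclear
        shared = list(ds.individuals)
        provenance = "mito_sites" if mito is not None else "nuc_sites"

    loci: list[str] = []
    ploidy: list[int] = []
    n_states: list[int] = []
    blocks: list[np.ndarray] = []  # each (n_ind, 2)

    def seq_index(ds: AlignedDataset) -> dict[tuple[str, int], int]:
        return {(ind, al): i for i, (ind, al, _) in enumerate(ds.sequences)}

    if mito is not None:
        idx = seq_index(mito)
        excl = set(mito_filter.excluded_sites) if mito_filter is not None else None
        for col, codes, ns in _polymorphic_codes(mito, gap_mode, excl):
            loci.append(f"mito_{col}")
            ploidy.append(1)
            n_states.append(ns)
            block = np.full((len(shared), 2), MISSING, dtype=int)
            for r, ind in enumerate(shared):
                block[r, 0] = codes[idx[(ind, 0)]]
            blocks.append(block)
    if nuclear is not None:
        idx = seq_index(nuclear)
        excl = set(nuclear_filter.excluded_sites) if nuclear_filter is not None else None
        for col, codes, ns in _polymorphic_codes(nuclear, gap_mode, excl):
            loci.append(f"nuc_{col}")
            ploidy.append(2)
            n_states.append(ns)
            block = np.full((len(shared), 2), MISSING, dtype=int)
            for r, ind in enumerate(shared):
                block[r, 0] = codes[idx[(ind, 0)]]
                block[r, 1] = codes[idx[(ind, 1)]]
            blocks.append(block)
        if indels is not None:
            key_idx = {k: i for i, k in enumerate(indels.allele_keys)}
            for sid, _interval, states in indels.series:
                if sid in indels.monomorphic:
                    continue
                loci.append(f"indel_{sid}")
                ploidy.append(2)
                n_states.append(2)
                block = np.full((len(shared), 2), MISSING, dtype=int)
                for r, ind in enumerate(shared):
                    block[r, 0] = states[key_idx[(ind, 0)]]
                    block[r, 1] = states[key_idx[(ind, 1)]]
                blocks.append(block)

    meta_ds = nuclear if nuclear is not None else mito
    smap = meta_ds.sample_map()
    if mito is not None and nuclear is not None:
        smap = {**mito.sample_map(), **nuclear.sample_map()}
    alleles = (
        np.stack(blocks, axis=1) if blocks else np.empty((len(shared), 0, 2), dtype=int)
    )
    return GenotypeMatrix(
        individuals=tuple(shared),
        isolates=tuple(smap[i].isolate_id for i in shared),
        loci=tuple(loci),
        ploidy=tuple(ploidy),
        n_states=tuple(n_states),
        alleles=alleles,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------

def _flatten(matrix: GenotypeMatrix):
    ind_idx, loc_idx, codes = [], [], []
    A = matrix.alleles
    for l in range(matrix.n_loci):
        slots = 1 if matrix.ploidy[l] == 1 else 2
        for s in range(slots):
            col = A[:, l, s]
            ok = col != MISSING
            ind_idx.append(np.where(ok)[0])
            loc_idx.append(np.full(ok.sum(), l))
            codes.append(col[ok])
    if not ind_idx:
        return (np.empty(0, int),) * 3
    return (
        np.concatenate(ind_idx),
        np.concatenate(loc_idx),
        np.concatenate(codes),
    )


def _kmeans_init(matrix: GenotypeMatrix, K: int, rng: np.random.Generator) -> np.ndarray:
    """Per-individual cluster seeds from k-means++ on one-hot allele
    profiles (a handful of Lloyd iterations); reduces mode-trapping of
    short chains without biasing the stationary distribution."""
    n, L = matrix.n_individuals, matrix.n_loci
    Amax = max(matrix.n_states)
    X = np.zeros((n, L * Amax))
    A = matrix.alleles
    for s in range(2):
        col = A[:, :, s]
        ok = col != MISSING
        rows, locs = np.nonzero(ok)
        X[rows, locs * Amax + col[rows, locs]] += 1.0
    # normalize per locus by copy count to keep haploid/diploid comparable
    centers = [X[rng.integers(n)]]
    for _ in range(K - 1):
        d2 = np.min([((X - c) ** 2).sum(axis=1) for c in centers], axis=0)
        tot = d2.sum()
        probs = d2 / tot if tot > 0 else np.full(n, 1.0 / n)
        centers.append(X[rng.choice(n, p=probs)])
    C = np.array(centers)
    lab = np.zeros(n, dtype=int)
    for _ in range(8):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        new = d2.argmin(axis=1)
        if (new == lab).all():
            break
        lab = new
        for k in range(K):
            if (lab == k).any():
                C[k] = X[lab == k].mean(axis=0)
    return lab


def run_admixture(
    matrix: GenotypeMatrix,
    K: int,
    burn_in: int = 10_000,
    reps: int = 50_000,
    seed: int = 0,
    model: str = "admixture",
    lambda_prior: float = 1.0,
    alpha_init: float = 1.0,
    alpha_max: float = 10.0,
    alpha_sd: float = 0.1,
    init: str = "kmeans",
    engine: str = "auto",
) -> ClusterRun:
    """Gibbs sampler for the admixture model; returns posterior means.

    ``reps`` is the total sweep count including ``burn_in``; estimates use
    the retained reps - burn_in sweeps.  model='no_admixture' constrains
    each individual to a single cluster of origin.  ``init`` is 'kmeans'
    (seeded k-means++ assignment start, the default) or 'random'.
    """
    n = matrix.n_individuals
    L = matrix.n_loci
    if n == 0 or L == 0:
        raise ClusteringError("empty genotype matrix")
    if K < 1:
        raise ClusteringError("K must be >= 1")
    if K > n:
        raise ClusteringError(f"K={K} exceeds number of individuals {n}")
    if reps <= burn_in or burn_in < 1:
        raise ClusteringError("need reps > burn_in >= 1")
    rng = np.random.default_rng(seed)
    ind_idx, loc_idx, codes = _flatten(matrix)
    M = len(codes)
    Amax = max(matrix.n_states)
    valid = np.zeros((L, Amax), dtype=bool)
    for l in range(L):
        valid[l, : matrix.n_states[l]] = True

    if init == "kmeans" and K > 1:
        lab = _kmeans_init(matrix, K, rng)
        Z = lab[ind_idx].copy()
    else:
        Z = rng.integers(0, K, size=M)
    flat_la0 = loc_idx * Amax + codes

    if engine == "auto":
        engine = "numba" if _HAVE_NUMBA else "numpy"
    if engine == "numba":
        Q_mean, P_flat, alpha_mean, ll_mean, ll_var = _gibbs_kernel(
            ind_idx.astype(np.int64),
            flat_la0.astype(np.int64),
            n, L, Amax, K,
            np.asarray(matrix.n_states, dtype=np.int64),
            Z.astype(np.int64),
            burn_in, reps,
            lambda_prior, alpha_init, alpha_max, alpha_sd,
            1 if model == "no_admixture" else 0,
            int(seed) % (2**31 - 1),
        )
        Q_mean = Q_mean / Q_mean.sum(axis=1, keepdims=True)
        return ClusterRun(
            K=K,
            Q=Q_mean,
            P=P_flat.reshape(K, L, Amax),
            alpha=float(alpha_mean),
            lnPD=float(ll_mean - ll_var / 2.0),
            seed=seed,
            mcmc=(burn_in, reps),
            individuals=matrix.individuals,
        )
    alpha = alpha_init
    Q = np.full((n, K), 1.0 / K)
    copies_per_ind = np.bincount(ind_idx, minlength=n).astype(float)

    Q_sum = np.zeros((n, K))
    P_sum = np.zeros((K, L, Amax))
    alpha_sum = 0.0
    ll_sum = 0.0
    ll_sq = 0.0
    kept = 0
    flat_la = loc_idx * Amax + codes  # index into (L*Amax) per observation

    LA = L * Amax
    for sweep in range(reps):
        # P | Z
        counts = np.bincount(Z * LA + flat_la, minlength=K * LA).reshape(K, L, Amax)
        g = rng.gamma(lambda_prior + counts)
        g *= valid[None, :, :]
        P = g / g.sum(axis=2, keepdims=True)
        # Q | Z
        qcounts = np.bincount(ind_idx * K + Z, minlength=n * K).reshape(n, K).astype(float)
        if model == "admixture" and K > 1:
            gq = rng.gamma(alpha + qcounts)
            Q = gq / gq.sum(axis=1, keepdims=True)
        elif K == 1:
            Q = np.ones((n, 1))
        else:  # no_admixture: one origin per individual
            logp = np.zeros((n, K))
            logP = np.log(np.maximum(P.reshape(K, L * Amax), 1e-300))
            for k in range(K):
                np.add.at(logp[:, k], ind_idx, logP[k, flat_la])
            logp -= logp.max(axis=1, keepdims=True)
            w = np.exp(logp)
            w /= w.sum(axis=1, keepdims=True)
            pick = (w.cumsum(axis=1) > rng.random((n, 1))).argmax(axis=1)
            Q = np.zeros((n, K))
            Q[np.arange(n), pick] = 1.0
        # Z | P, Q
        Pobs = P.reshape(K, L * Amax)[:, flat_la]  # (K, M)
        probs = Q[ind_idx].T * Pobs  # (K, M)
        tot = probs.sum(axis=0)
        tot[tot == 0] = 1.0
        cum = np.cumsum(probs / tot, axis=0)
        u = rng.random(M)
        Z = (cum > u).argmax(axis=0)
        # alpha | Q (random-walk Metropolis, uniform prior on (0, alpha_max])
        if model == "admixture" and K > 1:
            prop = alpha + rng.normal(0.0, alpha_sd)
            if 0 < prop <= alpha_max:
                logq = np.log(np.maximum(Q, 1e-300)).sum()
                from scipy.special import gammaln

                def dir_ll(a):
                    return n * (gammaln(K * a) - K * gammaln(a)) + (a - 1) * logq

                if np.log(rng.random()) < dir_ll(prop) - dir_ll(alpha):
                    alpha = prop
        if sweep >= burn_in:
            mix = (Q[ind_idx].T * Pobs).sum(axis=0)
            ll = float(np.log(np.maximum(mix, 1e-300)).sum())
            Q_sum += Q
            P_sum += P
            alpha_sum += alpha
            ll_sum += ll
            ll_sq += ll * ll
            kept += 1

    Q_mean = Q_sum / kept
    Q_mean /= Q_mean.sum(axis=1, keepdims=True)
    ll_mean = ll_sum / kept
    ll_var = max(ll_sq / kept - ll_mean**2, 0.0)
    lnPD = ll_mean - ll_var / 2.0
    return ClusterRun(
        K=K,
        Q=Q_mean,
        P=P_sum / kept,
        alpha=alpha_sum / kept,
        lnPD=lnPD,
        seed=seed,
        mcmc=(burn_in, reps),
        individuals=matrix.individuals,
    )


# ---------------------------------------------------------------------------
# deltaK model choice
# ---------------------------------------------------------------------------

def evanno_delta_k(
    lnPD_mean: dict[int, float], lnPD_sd: dict[int, float]
) -> dict[int, float]:
    """deltaK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) for interior K.

    K with zero between-replicate sd get nan (undefined)."""
    ks = sorted(lnPD_mean)
    out: dict[int, float] = {}
    for k in ks[1:-1]:
        num = abs(lnPD_mean[k + 1] - 2 * lnPD_mean[k] + lnPD_mean[k - 1])
        sd = lnPD_sd[k]
        out[k] = num / sd if sd > 0 else float("nan")
    return out


def select_k(
    matrix: GenotypeMatrix,
    K_range: Sequence[int] = (1, 2, 3, 4),
    replicates: int = 5,
    burn_in: int = 10_000,
    reps: int = 50_000,
    seed: int = 0,
    model: str = "admixture",
    peak_tolerance: float = 0.05,
    dominance: float = 4.0,
) -> KSelection:
    """Run replicate samplers across K and choose K by deltaK.

    Ties within ``peak_tolerance`` of the maximum resolve to the smallest K
    (with a note).  The choice is flagged unreliable when the top peak is
    less than ``dominance`` times the second one (no dominant peak, e.g. a
    panmictic sample).  Replicate r of a given K uses seed + r.
    """
    Ks = sorted(set(int(k) for k in K_range))
    if len(Ks) < 4:
        raise ClusteringError("K_range must cover >=4 consecutive values for deltaK")
    if replicates < 3:
        raise ClusteringError("need >=3 replicates per K for deltaK")
    if matrix.n_loci == 0:
        return KSelection(
            tested_Ks=tuple(Ks), replicates=replicates, lnPD_mean={}, lnPD_sd={},
            deltaK={}, chosen_K=1, reliable=True,
            note="no polymorphic loci: K=1 by definition", runs={},
        )
    runs: dict[int, tuple] = {}
    means: dict[int, float] = {}
    sds: dict[int, float] = {}
    for K in Ks:
        rs = tuple(
            run_admixture(matrix, K, burn_in=burn_in, reps=reps,
                          seed=seed + 1000 * K + r, model=model)
            for r in range(replicates)
        )
        runs[K] = rs
        vals = np.array([r.lnPD for r in rs])
        means[K] = float(vals.mean())
        sds[K] = float(vals.std(ddof=1))
    dk = evanno_delta_k(means, sds)
    notes = []
    finite = {k: v for k, v in dk.items() if np.isfinite(v)}
    if not finite:
        chosen, reliable = Ks[0], False
        notes.append("deltaK undefined everywhere (zero replicate sd)")
    else:
        best_val = max(finite.values())
        peaks = [k for k, v in finite.items() if v >= (1 - peak_tolerance) * best_val]
        chosen = min(peaks)
        if len(peaks) > 1:
            notes.append(f"{len(peaks)} similar peaks at K={sorted(peaks)}; smallest kept")
        others = sorted(finite.values())[:-1]
        second = others[-1] if others else 0.0
        reliable = best_val >= dominance * second if second > 0 else True
        if not reliable:
            notes.append("no dominant deltaK peak; choice unreliable")
    nan_ks = [k for k, v in dk.items() if not np.isfinite(v)]
    if nan_ks:
        notes.append(f"deltaK undefined at K={nan_ks} (zero replicate sd)")
    # a sharp deltaK peak with no confidently assigned individuals is not
    # evidence of structure (panmictic data give diffuse Q rows)
    if chosen > 1 and chosen in runs:
        best = max(runs[chosen], key=lambda r: r.lnPD)
        support = float((best.Q.max(axis=1) >= 0.7).mean())
        if support < 0.2:
            reliable = False
            notes.append(
                f"only {100 * support:.0f}% of individuals confidently "
                "assigned; choice unreliable"
            )
    return KSelection(
        tested_Ks=tuple(Ks),
        replicates=replicates,
        lnPD_mean=means,
        lnPD_sd=sds,
        deltaK=dk,
        chosen_K=int(chosen),
        reliable=bool(reliable),
        note="; ".join(notes),
        runs=runs,
    )


# ---------------------------------------------------------------------------
# Hierarchical protocol
# ---------------------------------------------------------------------------

def hierarchical_analysis(
    matrix: GenotypeMatrix,
    K_range: Sequence[int] = (1, 2, 3, 4),
    threshold: float = 0.7,
    min_n: int = 10,
    max_depth: int = 3,
    replicates: int = 3,
    burn_in: int = 2_000,
    reps: int = 6_000,
    seed: int = 0,
    subset_rule: str = "assignment_threshold",
    homogeneity: float = 0.9,
) -> HierarchicalResult:
    """Recursive model choice on subsets defined by individual assignment.

    At each node select K; if K > 1, individuals whose maximum ancestry is
    >= ``threshold`` form per-cluster subsets (rule 'assignment_threshold'),
    or whole isolates whose mean majority ancestry is >= ``homogeneity``
    follow their majority cluster (rule 'homogeneous_isolates'); subsets
    with >= ``min_n`` individuals are analysed one level down.
    """

    def analyse(label: str, sub: GenotypeMatrix, depth: int) -> HierarchicalNode:
        if sub.n_individuals < max(min_n, max(K_range) + 1):
            return HierarchicalNode(label, sub.individuals, None, None, (), (),
                                    note="below min_n: leaf")
        sel = select_k(sub, K_range, replicates=replicates, burn_in=burn_in,
                       reps=reps, seed=seed + depth * 7919)
        if sel.chosen_K <= 1 or not sel.runs:
            return HierarchicalNode(label, sub.individuals, sel, None, (), (),
                                    note="K=1: leaf")
        run = sel.best_run()
        maj = run.Q.argmax(axis=1)
        qmax = run.Q.max(axis=1)
        children = []
        unassigned = []
        if subset_rule == "assignment_threshold":
            member_ids = {k: [] for k in range(sel.chosen_K)}
            for i, ind in enumerate(sub.individuals):
                if qmax[i] >= threshold:
                    member_ids[maj[i]].append(ind)
                else:
                    unassigned.append(ind)
        elif subset_rule == "homogeneous_isolates":
            member_ids = {k: [] for k in range(sel.chosen_K)}
            iso_rows: dict[str, list[int]] = {}
            for i, iso in enumerate(sub.isolates):
                iso_rows.setdefault(iso, []).append(i)
            for iso, rows in iso_rows.items():
                mean_major = float(np.mean(qmax[rows]))
                if mean_major >= homogeneity:
                    k = int(np.bincount(maj[rows]).argmax())
                    member_ids[k].extend(sub.individuals[i] for i in rows)
                else:
                    unassigned.extend(sub.individuals[i] for i in rows)
        else:
            raise ClusteringError(f"unknown subset_rule {subset_rule!r}")
        if depth < max_depth:
            for k in sorted(member_ids):
                ids = member_ids[k]
                if len(ids) >= min_n:
                    children.append(analyse(f"{label}/k{k}", sub.subset(ids), depth + 1))
                elif ids:
                    children.append(
                        HierarchicalNode(f"{label}/k{k}", tuple(ids), None, None,
                                         (), (), note="subset below min_n")
                    )
        return HierarchicalNode(
            label, sub.individuals, sel, run, tuple(unassigned), tuple(children)
        )

    root = analyse("root", matrix, 0)
    return HierarchicalResult(root=root, subset_rule=subset_rule, threshold=threshold)


# ---------------------------------------------------------------------------
# Heterozygote flags and run comparison
# ---------------------------------------------------------------------------

def flag_intercluster_heterozygotes(
    run: ClusterRun, band: tuple[float, float] = (0.405, 0.595)
) -> list[tuple[str, tuple[int, int], tuple[float, float]]]:
    """Individuals whose two largest ancestry components both fall inside
    ``band`` (default the 0.450/0.550 +/- flagging band): read as
    inter-cluster heterozygotes (F1-like hybrids).  Returns
    (individual_id, (cluster_i, cluster_j), (q_i, q_j))."""
    lo, hi = band
    out = []
    if run.K < 2:
        return out
    for i, ind in enumerate(run.individuals):
        order = np.argsort(run.Q[i])[::-1]
        q1, q2 = run.Q[i, order[0]], run.Q[i, order[1]]
        if lo <= q1 <= hi and lo <= q2 <= hi:
            pair = tuple(sorted((int(order[0]), int(order[1]))))
            out.append((ind, pair, (float(run.Q[i, pair[0]]), float(run.Q[i, pair[1]]))))
    return out


def match_labels(Q_ref: np.ndarray, Q_other: np.ndarray) -> np.ndarray:
    """Column permutation of Q_other maximizing majority-assignment agreement
    with Q_ref (Hungarian on the confusion matrix of majority labels)."""
    ka, kb = Q_ref.shape[1], Q_other.shape[1]
    k = max(ka, kb)
    conf = np.zeros((k, k))
    a = Q_ref.argmax(axis=1)
    b = Q_other.argmax(axis=1)
    for x, y in zip(a, b):
        conf[x, y] += 1
    row, col = linear_sum_assignment(-conf)
    perm = np.empty(k, dtype=int)
    perm[col] = row
    return perm


@dataclass(frozen=True)
class ConcordanceReport:
    same_k: bool
    agreement: float
    changed_individuals: tuple[str, ...]


def compare_clusterings(
    full: tuple[KSelection, ClusterRun],
    filtered: tuple[KSelection, ClusterRun],
) -> ConcordanceReport:
    """Concordance of two clusterings of the same individuals: equality of
    the selected K, best label-permutation agreement of majority
    assignments, and the individuals changing majority cluster."""
    sel_a, run_a = full
    sel_b, run_b = filtered
    if run_a.individuals != run_b.individuals:
        raise ClusteringError("clustering runs cover different individuals")
    perm = match_labels(run_a.Q, run_b.Q)
    a = run_a.Q.argmax(axis=1)
    b_raw = run_b.Q.argmax(axis=1)
    b = perm[b_raw]
    same = a == b
    changed = tuple(ind for ind, ok in zip(run_a.individuals, same) if not ok)
    return ConcordanceReport(
        same_k=sel_a.chosen_K == sel_b.chosen_K,
        agreement=float(same.mean()),
        changed_individuals=changed,
    )
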