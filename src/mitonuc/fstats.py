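"""AMOVA-based F-statistics on sequence data: pairwise Phi_ST, hierarchical
AMOVA and F_IS, with permutation tests.

The decomposition follows Excoffier's analysis of molecular variance on the
matrix of pairwise sequence differences (the number of differing sites,
entering as squared Euclidean distances, as in Arlequin's haplotype-distance
AMOVA).  The design is fully nested -- groups / populations (isolates) within
groups / individuals within populations / allele copies within individuals --
with unbalanced-design coefficients, so negative variance components are
possible and are reported, not truncated.

Permutation tests use, by default, the *genotype* as the randomization unit:
both alleles of a diploid individual move together when individuals are
permuted among populations.  This is the appropriate scheme when
Hardy-Weinberg equilibrium cannot be assumed within units; the allele-unit
scheme is available for comparison.  F_IS significance permutes allele
copies among individuals within populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


from .seqdata import AlignedDataset, GapMode, Ploidy

__all__ = [
    "FstResult",
    "AmovaResult",
    "distance_matrix",
    "pairwise_fst",
    "pairwise_fst_from_distances",
    "amova",
    "fis",
]


class FstatsError(ValueError):
    pass


@dataclass(frozen=True)
class FstResult:
    unit_a: str
    unit_b: str
    phi_st: float
    p_value: float | None
    n_permutations: int
    randomization_unit: str  # genotype | allele | individual


@dataclass(frozen=True)
class AmovaResult:
    level_names: tuple[str, ...]  # strata, coarsest first, then "within"
    df: tuple[int, ...]
    sums_of_squares: tuple[float, ...]
    variance_components: tuple[float, ...]
    percentages: tuple[float, ...]
    phi: dict[str, float]
    p_values: dict[str, float] = field(default_factory=dict)
    n_permutations: int = 0
    notes: tuple[str, ...] = ()

    @property
    def f_is(self) -> float | None:
        return self.phi.get("Phi_IS")


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def distance_matrix(seqs: Sequence[str], gap_mode: GapMode | str = GapMode.ignore_gap_columns) -> np.ndarray:
    """Square matrix of pairwise difference counts (N ignored site-wise,
    gaps per gap_mode)."""
    gap_mode = GapMode(gap_mode)
    L = len(seqs[0])
    mat = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
    if gap_mode == GapMode.ignore_gap_columns:
        mat = mat[:, ~(mat == b"-").any(axis=0)]
    n = mat.shape[0]
    D = np.zeros((n, n))
    valid = mat != b"N"
    for i in range(n):
        diff = (mat[i] != mat[i + 1 :]) & valid[i] & valid[i + 1 :]
        D[i, i + 1 :] = diff.sum(axis=1)
    return D + D.T


# ---------------------------------------------------------------------------
# Nested variance decomposition
# ---------------------------------------------------------------------------

def _ss_of(D: np.ndarray, idx: np.ndarray) -> float:
    if len(idx) == 0:
        return 0.0
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum()) / 2.0 / len(idx)


def _nested_components(
    D: np.ndarray, levels: Sequence[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components for a fully nested design.

    ``levels``: integer label arrays over the N copies, coarsest first; units
    within the finest level are the copies themselves.  Returns
    (df, SS, variance components) with one stratum per level ("among level-j
    units within level-(j-1) units") plus the final within stratum.
    """
    N = D.shape[0]
    k = len(levels)
    all_idx = np.arange(N)
    # unique units per level and their member indices
    unit_idx: list[dict[int, np.ndarray]] = []
    for lab in levels:
        d: dict[int, np.ndarray] = {}
        for u in np.unique(lab):
            d[int(u)] = all_idx[lab == u]
        unit_idx.append(d)
    ss_level = []  # sum over units at level j of SS(unit)
    for d in unit_idx:
        ss_level.append(sum(_ss_of(D, idx) for idx in d.values()))
    ss_total = _ss_of(D, all_idx)
    SS = []
    df = []
    prev_ss = ss_total
    prev_count = 1
    for j in range(k):
        nu = len(unit_idx[j])
        SS.append(prev_ss - ss_level[j])
        df.append(nu - prev_count)
        prev_ss = ss_level[j]
        prev_count = nu
    SS.append(ss_level[-1])
    df.append(N - prev_count)
    SS = np.asarray(SS)
    df = np.asarray(df, dtype=float)

    # coefficients: A(level, M) = sum over units x at `level` of
    # (sum of N_y^2 over M-units y inside x) / N_x ; level -1 = whole dataset
    sizes = [
        {u: len(idx) for u, idx in d.items()} for d in unit_idx
    ]

    def A(level: int, m: int) -> float:
        if level == -1:
            return sum(s**2 for s in sizes[m].values()) / N
        tot = 0.0
        for u, idx in unit_idx[level].items():
            labm = levels[m][idx]
            _, cnt = np.unique(labm, return_counts=True)
            tot += float((cnt.astype(float) ** 2).sum()) / len(idx)
        return tot

    # E[MS_j] = sigma_w^2 + sum_{m>=j} c[j,m] sigma_m^2  (strata j=0..k-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        MS = np.where(df > 0, SS / df, 0.0)
    sigma = np.zeros(k + 1)
    sigma[k] = MS[k] if df[k] > 0 else 0.0
    C = np.zeros((k, k))
    for j in range(k):
        if df[j] <= 0:
            continue
        for m in range(j, k):
            C[j, m] = (A(j, m) - A(j - 1, m)) / df[j]
    for j in range(k - 1, -1, -1):
        if df[j] <= 0:
            sigma[j] = 0.0
            continue
        acc = MS[j] - sigma[k]
        for m in range(j + 1, k):
            acc -= C[j, m] * sigma[m]
        sigma[j] = acc / C[j, j]
    return df.astype(int), SS, sigma


def _phi_stats(sigma: np.ndarray, level_names: Sequence[str]) -> dict[str, float]:
    total = float(sigma.sum())
    k = len(sigma) - 1
    phi: dict[str, float] = {}
    if total == 0:
        return {name: 0.0 for name in _phi_names(level_names, k)}
    if k == 1:  # among units / within units
        phi["Phi_ST"] = sigma[0] / total
    elif k == 2:
        if level_names[-2].startswith("individual"):
            # populations / individuals / within individuals
            phi["Phi_ST"] = sigma[0] / total
            phi["Phi_IS"] = sigma[1] / (sigma[1] + sigma[2]) if sigma[1] + sigma[2] != 0 else 0.0
            phi["Phi_IT"] = (sigma[0] + sigma[1]) / total
        else:
            # groups / populations / within populations (haploid)
            phi["Phi_CT"] = sigma[0] / total
            phi["Phi_SC"] = sigma[1] / (sigma[1] + sigma[2]) if sigma[1] + sigma[2] != 0 else 0.0
            phi["Phi_ST"] = (sigma[0] + sigma[1]) / total
    elif k == 3:
        phi["Phi_CT"] = sigma[0] / total
        rest = sigma[1] + sigma[2] + sigma[3]
        phi["Phi_SC"] = sigma[1] / rest if rest != 0 else 0.0
        phi["Phi_ST"] = (sigma[0] + sigma[1]) / total
        phi["Phi_IS"] = sigma[2] / (sigma[2] + sigma[3]) if sigma[2] + sigma[3] != 0 else 0.0
        phi["Phi_IT"] = (sigma[0] + sigma[1] + sigma[2]) / total
    return phi


def _phi_names(level_names, k):
    if k == 1:
        return ["Phi_ST"]
    if k == 2:
        return (["Phi_ST", "Phi_IS", "Phi_IT"]
                if level_names[-2].startswith("individual")
                else ["Phi_CT", "Phi_SC", "Phi_ST"])
    return ["Phi_CT", "Phi_SC", "Phi_ST", "Phi_IS", "Phi_IT"]


# ---------------------------------------------------------------------------
# Pairwise Phi_ST
# ---------------------------------------------------------------------------

def pairwise_fst_from_distances(
    D: np.ndarray,
    pop: np.ndarray,
    individual: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    unit: str = "genotype",
    unit_names: tuple[str, str] = ("A", "B"),
) -> FstResult:
    """Phi_ST between two units from a precomputed difference matrix.

    ``pop`` is a 0/1 label per copy; ``individual`` maps copies to genotype
    units (both alleles of an individual permute together when
    unit='genotype').  p = (1 + #{perm >= obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise FstatsError("n_perm must be >= 1")
    pop = np.asarray(pop)
    if individual is None or unit == "allele":
        individual = np.arange(len(pop))
    individual = np.asarray(individual)

    def stat(pop_labels: np.ndarray) -> float:
        _, _, sigma = _nested_components(D, [pop_labels])
        total = sigma.sum()
        return float(sigma[0] / total) if total != 0 else 0.0

    obs = stat(pop)
    rng = np.random.default_rng(seed)
    # permute at the genotype level: each individual keeps its copies together
    uniq_ind = np.unique(individual)
    ind_pop = np.array([pop[individual == u][0] for u in uniq_ind])
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(ind_pop)
        new_pop = np.empty_like(pop)
        for u, pl in zip(uniq_ind, perm):
            new_pop[individual == u] = pl
        if stat(new_pop) >= obs - 1e-12:
            ge += 1
    p = (ge + 1) / (n_perm + 1)
    return FstResult(
        unit_a=unit_names[0],
        unit_b=unit_names[1],
        phi_st=obs,
        p_value=p,
        n_permutations=n_perm,
        randomization_unit=unit if unit != "genotype" else "genotype",
    )


def pairwise_fst(
    dataset: AlignedDataset,
    unit_a: str,
    unit_b: str,
    gap_mode: GapMode | str = GapMode.ignore_gap_columns,
    n_perm: int = 1000,
    seed: int = 0,
    unit: str = "genotype",
) -> FstResult:
    """Pairwise Phi_ST between two isolates of a dataset with permutation p.

    For the haploid locus the randomization unit is the individual; for the
    diploid locus the genotype (default) or single alleles (unit='allele').
    """
    smap = dataset.sample_map()
    rows = [
        (ind, res)
        for ind, _, res in dataset.sequences
        if smap[ind].isolate_id in (unit_a, unit_b)
    ]
    seqs = [r for _, r in rows]
    inds = [i for i, _ in rows]
    if len({i for i, r in rows if smap[i].isolate_id == unit_a}) < 1 or len(seqs) < 4:
        raise FstatsError("both units need at least 2 allele sequences")
    D = distance_matrix(seqs, gap_mode)
    pop = np.array([0 if smap[i].isolate_id == unit_a else 1 for i in inds])
    uniq = {u: k for k, u in enumerate(dict.fromkeys(inds))}
    individual = np.array([uniq[i] for i in inds])
    runit = "individual" if dataset.ploidy == Ploidy.haploid else unit
    res = pairwise_fst_from_distances(
        D, pop, individual, n_perm=n_perm, seed=seed, unit=runit,
        unit_names=(unit_a, unit_b),
    )
    return res


# ---------------------------------------------------------------------------
# Hierarchical AMOVA
# ---------------------------------------------------------------------------

def amova(
    dataset: AlignedDataset,
    grouping: dict[str, str] | Callable[[str], str] | None = None,
    gap_mode: GapMode | str = GapMode.ignore_gap_columns,
    n_perm: int = 1000,
    seed: int = 0,
) -> AmovaResult:
    """Nested AMOVA: [groups /] isolates [/ individuals] / within.

    ``grouping`` maps isolate_id -> group label (dict or callable); omit it
    for a two-level design (isolates as top level).  Diploid data add an
    among-individuals stratum whose Phi_IS is the inbreeding coefficient
    F_IS.  Per-stratum permutation schemes: populations among groups
    (Phi_CT), individuals among populations within groups (Phi_SC),
    individuals among populations (Phi_ST), alleles among individuals within
    populations (Phi_IS).
    """
    smap = dataset.sample_map()
    inds = [ind for ind, _, _ in dataset.sequences]
    seqs = [res for _, _, res in dataset.sequences]
    D = distance_matrix(seqs, gap_mode)
    iso_of = np.array([smap[i].isolate_id for i in inds])
    isolates = list(dict.fromkeys(iso_of))
    pop = np.array([isolates.index(x) for x in iso_of])
    uniq_ind = list(dict.fromkeys(inds))
    individual = np.array([uniq_ind.index(i) for i in inds])
    diploid = dataset.ploidy == Ploidy.diploid

    notes = []
    group = None
    if grouping is not None:
        gfun = grouping.get if isinstance(grouping, dict) else grouping
        glabels = [gfun(x) for x in isolates]
        if any(g is None for g in glabels):
            missing = [x for x, g in zip(isolates, glabels) if g is None]
            raise FstatsError(f"grouping missing for isolates {missing}")
        gnames = list(dict.fromkeys(glabels))
        if len(gnames) < 2:
            notes.append("single group: among-groups level omitted")
        else:
            group = np.array([gnames.index(gfun(x)) for x in iso_of])

    levels: list[np.ndarray] = []
    names: list[str] = []
    if group is not None:
        levels.append(group)
        names.append("among_groups")
    levels.append(pop)
    names.append("among_isolates_within_groups" if group is not None else "among_isolates")
    if diploid:
        levels.append(individual)
        names.append("among_individuals_within_isolates")
    names.append("within_individuals" if diploid else "within_isolates")

    df, SS, sigma = _nested_components(D, levels)
    total = float(sigma.sum())
    pct = tuple(100.0 * s / total if total != 0 else 0.0 for s in sigma)
    phi = _phi_stats(sigma, names)

    # permutation p-values
    rng = np.random.default_rng(seed)
    p_values: dict[str, float] = {}
    if n_perm >= 1:
        p_values = _amova_pvalues(
            D, levels, names, phi, group, pop, individual, diploid, n_perm, rng
        )
    return AmovaResult(
        level_names=tuple(names),
        df=tuple(int(x) for x in df),
        sums_of_squares=tuple(float(x) for x in SS),
        variance_components=tuple(float(x) for x in sigma),
        percentages=pct,
        phi=phi,
        p_values=p_values,
        n_permutations=n_perm,
        notes=tuple(notes),
    )


def _amova_pvalues(D, levels, names, phi, group, pop, individual, diploid, n_perm, rng):
    n_copies = D.shape[0]
    uniq_ind = np.unique(individual)
    copies_of_ind = {u: np.where(individual == u)[0] for u in uniq_ind}
    ind_pop = np.array([pop[copies_of_ind[u][0]] for u in uniq_ind])
    counts = {k: phi.get(k) for k in phi}
    ge = {k: 0 for k in phi}

    def components(levs):
        _, _, sigma = _nested_components(D, levs)
        return sigma

    for _ in range(n_perm):
        # scheme 1: individuals among populations (Phi_ST)
        perm_pop_of_ind = rng.permutation(ind_pop)
        new_pop = np.empty(n_copies, dtype=int)
        for u, pl in zip(uniq_ind, perm_pop_of_ind):
            new_pop[copies_of_ind[u]] = pl
        levs = []
        if group is not None:
            # group follows the population label
            pop_group = {}
            for p_lab, g_lab in zip(pop, group):
                pop_group[int(p_lab)] = int(g_lab)
            levs.append(np.array([pop_group[int(x)] for x in new_pop]))
        levs.append(new_pop)
        if diploid:
            levs.append(individual)
        sig = components(levs)
        ph = _phi_stats(sig, names)
        if "Phi_ST" in phi and ph.get("Phi_ST", 0.0) >= phi["Phi_ST"] - 1e-12:
            ge["Phi_ST"] += 1
        if group is not None and "Phi_SC" not in phi:
            pass

        # scheme 2: populations among groups (Phi_CT)
        if group is not None and "Phi_CT" in phi:
            pops_list = np.unique(pop)
            pop_group = np.array([group[pop == p_][0] for p_ in pops_list])
            perm_g = rng.permutation(pop_group)
            gmap = {int(p_): int(g_) for p_, g_ in zip(pops_list, perm_g)}
            new_group = np.array([gmap[int(x)] for x in pop])
            levs = [new_group, pop] + ([individual] if diploid else [])
            ph = _phi_stats(components(levs), names)
            if ph.get("Phi_CT", 0.0) >= phi["Phi_CT"] - 1e-12:
                ge["Phi_CT"] += 1

        # scheme 3: individuals among populations within groups (Phi_SC)
        if group is not None and "Phi_SC" in phi:
            ind_group = np.array([group[copies_of_ind[u][0]] for u in uniq_ind])
            perm_pop2 = ind_pop.copy()
            for g_ in np.unique(ind_group):
                sel = ind_group == g_
                perm_pop2[sel] = rng.permutation(ind_pop[sel])
            new_pop2 = np.empty(n_copies, dtype=int)
            for u, pl in zip(uniq_ind, perm_pop2):
                new_pop2[copies_of_ind[u]] = pl
            levs = [group, new_pop2] + ([individual] if diploid else [])
            ph = _phi_stats(components(levs), names)
            if ph.get("Phi_SC", 0.0) >= phi["Phi_SC"] - 1e-12:
                ge["Phi_SC"] += 1
        elif "Phi_SC" in phi and group is None:
            pass

        # scheme 4: alleles among individuals within populations (F_IS)
        if diploid and "Phi_IS" in phi:
            new_ind = individual.copy()
            for p_ in np.unique(pop):
                sel = np.where(pop == p_)[0]
                new_ind[sel] = individual[sel][rng.permutation(len(sel))]
            levs = ([group] if group is not None else []) + [pop, new_ind]
            ph = _phi_stats(components(levs), names)
            if ph.get("Phi_IS", 0.0) >= phi["Phi_IS"] - 1e-12:
                ge["Phi_IS"] += 1

    return {
        k: (ge[k] + 1) / (n_perm + 1)
        for k in ge
        if k in ("Phi_ST", "Phi_CT", "Phi_SC", "Phi_IS") and k in phi
    }


# ---------------------------------------------------------------------------
# F_IS per unit
# ---------------------------------------------------------------------------

def fis(
    dataset: AlignedDataset,
    units: dict[str, list[str]] | None = None,
    gap_mode: GapMode | str = GapMode.ignore_gap_columns,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[str, tuple[float | None, float | None]]:
    """Per-unit F_IS (+ permutation p) at the diploid locus.

    ``units`` maps unit_id -> individual ids (e.g. isolates, or inferred
    clusters restricted to individuals assigned above a threshold); default
    is the isolates of the dataset.  Units with <2 individuals give
    (None, None).  p permutes alleles among individuals within the unit.
    """
    if dataset.ploidy != Ploidy.diploid:
        raise FstatsError("F_IS requires the diploid locus")
    smap = dataset.sample_map()
    if units is None:
        units = {}
        for s in dataset.samples:
            units.setdefault(s.isolate_id, []).append(s.individual_id)
    out: dict[str, tuple[float | None, float | None]] = {}
    rng = np.random.default_rng(seed)
    seq_of: dict[str, list[str]] = {}
    for ind, _, res in dataset.sequences:
        seq_of.setdefault(ind, []).append(res)
    for unit_id, members in units.items():
        members = [m for m in members if m in seq_of]
        if len(members) < 2:
            out[unit_id] = (None, None)
            continue
        seqs = []
        individual = []
        for k, m in enumerate(members):
            for res in seq_of[m]:
                seqs.append(res)
                individual.append(k)
        D = distance_matrix(seqs, gap_mode)
        individual = np.asarray(individual)

        def stat(ind_labels: np.ndarray) -> float:
            _, _, sigma = _nested_components(D, [ind_labels])
            tot = sigma.sum()
            return float(sigma[0] / tot) if tot != 0 else 0.0

        obs = stat(individual)
        if D.sum() == 0:
            out[unit_id] = (None, None)  # monomorphic: F_IS undefined
            continue
        ge = 0
        for _ in range(n_perm):
            if stat(individual[rng.permutation(len(individual))]) >= obs - 1e-12:
                ge += 1
        out[unit_id] = (obs, (ge + 1) / (n_perm + 1))
    return out
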