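"""Mismatch distributions and sudden-expansion demography.

The observed mismatch distribution is the histogram of pairwise nucleotide
differences over all unordered pairs of allele sequences (pairs, not
collapsed haplotypes, so frequencies weight the distribution).  It is
compared with the expectation under the sudden-expansion model of Rogers &
Harpending (1992): a population at mutation-scaled size theta0 grows
instantaneously to theta1 at time tau = 2*u*t before present (u = total
mutation rate over the fragment).  The probability that a random pair
differs at j sites is, with Fhat_j(theta) = theta^j / (1+theta)^(j+1) the
equilibrium geometric law,

    F_j(tau, theta0, theta1) = Fhat_j(theta1)
        + exp(-tau*(theta1+1)/theta1)
          * sum_{i<=j} tau^(j-i)/(j-i)! * (Fhat_i(theta0) - Fhat_i(theta1))

(the exact pair-coalescent solution of the two-epoch model).  Fitting
minimizes SSD = sum_j (f_j - F_j)^2 over the observed range by bounded
multi-start Nelder-Mead; the likelihood surface is ridge-like in
(theta1, tau), hence the theta1 cap (1e5, an effectively infinite
post-expansion size) and several seed-dependent starts.

Goodness of fit (SSD and Harpending's raggedness index) is assessed by
parametric bootstrap: coalescent samples of the same size are simulated
under the fitted expansion, each is refitted, and P is the fraction of
simulated statistics at least as large as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.signal import find_peaks
from scipy.special import gammaln

from .diversity import pairwise_differences
from .seqdata import GapMode, HaplotypeTable

__all__ = [
    "MismatchDistribution",
    "MismatchFit",
    "mismatch_distribution",
    "expected_mismatch",
    "fit_sudden_expansion",
    "goodness_of_fit",
    "raggedness_index",
    "classify_profile",
]

THETA1_CAP = 1e5


class MismatchError(ValueError):
    pass


@dataclass(frozen=True)
class MismatchDistribution:
    unit_id: str
    counts: tuple[int, ...]  # index j = number of pairwise differences
    n_pairs: int

    @property
    def frequencies(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float) / self.n_pairs

    @property
    def jmax(self) -> int:
        return len(self.counts) - 1


@dataclass(frozen=True)
class MismatchFit:
    tau: float
    theta0: float
    theta1: float
    SSD: float
    p_ssd: float | None = None
    raggedness: float | None = None
    p_raggedness: float | None = None
    profile: str | None = None  # uni | bi | 2h | 1h
    n_bootstrap: int | None = None


def mismatch_distribution(
    seqs: Sequence[str],
    gap_mode: GapMode | str = GapMode.ignore_gap_columns,
    unit_id: str = "",
) -> MismatchDistribution:
    seqs = list(seqs)
    if len(seqs) < 2:
        raise MismatchError("mismatch distribution needs >=2 allele sequences")
    d = pairwise_differences(seqs, gap_mode)
    counts = np.bincount(d)
    return MismatchDistribution(unit_id=unit_id, counts=tuple(int(c) for c in counts),
                                n_pairs=len(d))


# ---------------------------------------------------------------------------
# Sudden-expansion expectation and fit
# ---------------------------------------------------------------------------

def _geom(theta: float, jmax: int) -> np.ndarray:
    j = np.arange(jmax + 1)
    if theta <= 0:
        out = np.zeros(jmax + 1)
        out[0] = 1.0
        return out
    # theta^j/(1+theta)^(j+1), stable in logs for large theta
    return np.exp(j * np.log(theta) - (j + 1) * np.log1p(theta))


def expected_mismatch(tau: float, theta0: float, theta1: float, jmax: int) -> np.ndarray:
    """Expected pairwise-difference probabilities F_0..F_jmax under the
    sudden-expansion model (exact two-epoch pair coalescent)."""
    f1 = _geom(theta1, jmax)
    f0 = _geom(theta0, jmax)
    m = np.arange(jmax + 1)
    if tau == 0:
        return f0
    if theta1 <= 0:
        return f0  # theta1 -> 0 degenerates to the pre-expansion equilibrium
    c = (theta1 + 1.0) / theta1
    # log-stable Poisson-like weights exp(-c*tau) * tau^m / m!
    logw = -c * tau + m * np.log(tau) - gammaln(m + 1)
    w = np.exp(logw)
    diff = f0 - f1
    corr = np.convolve(diff, w)[: jmax + 1]
    return f1 + corr


def _ssd(freqs: np.ndarray, params: np.ndarray) -> float:
    tau, theta0, theta1 = params
    exp = expected_mismatch(tau, theta0, theta1, len(freqs) - 1)
    return float(((freqs - exp) ** 2).sum())


def fit_sudden_expansion(
    dist: MismatchDistribution,
    n_starts: int = 3,
    seed: int = 0,
    theta1_cap: float = THETA1_CAP,
    maxiter: int = 400,
) -> MismatchFit:
    """Least-squares fit of (tau, theta0, theta1) to the observed mismatch
    frequencies; bounded multi-start Nelder-Mead with seed-dependent starts."""
    freqs = dist.frequencies
    jmax = dist.jmax
    j = np.arange(jmax + 1)
    mean_j = float((freqs * j).sum())
    if dist.n_pairs < 1:
        raise MismatchError("empty distribution")
    if len(np.nonzero(freqs)[0]) == 1:
        warnings.warn(
            "degenerate mismatch distribution (all mass at one value); "
            "tau pinned near that value",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    bounds = [(0.0, max(4.0 * (jmax + 1), 10.0)), (0.0, 100.0), (0.0, theta1_cap)]
    starts = [np.array([max(mean_j, 1e-3), 0.5, 1000.0])]
    for _ in range(max(0, n_starts - 1)):
        starts.append(
            np.array(
                [
                    rng.uniform(0.0, max(2.0 * mean_j, 2.0)),
                    rng.uniform(0.0, max(mean_j, 1.0)),
                    10 ** rng.uniform(0.5, np.log10(theta1_cap)),
                ]
            )
        )
    best = None
    for x0 in starts:
        res = minimize(
            lambda p: _ssd(freqs, p),
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"maxiter": maxiter, "xatol": 1e-4, "fatol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau, theta0, theta1 = best.x
    return MismatchFit(tau=float(tau), theta0=float(theta0), theta1=float(theta1),
                       SSD=float(best.fun))


def raggedness_index(freqs: np.ndarray) -> float:
    """Harpending's raggedness r = sum_{i=1}^{d+1} (x_i - x_{i-1})^2 over
    normalized frequencies, with x_{d+1} = 0."""
    x = np.concatenate([np.asarray(freqs, dtype=float), [0.0]])
    return float(((x[1:] - x[:-1]) ** 2).sum())


# ---------------------------------------------------------------------------
# Parametric bootstrap
# ---------------------------------------------------------------------------

def _simulate_expansion_mismatch(
    n: int, tau: float, theta0: float, theta1: float, rng: np.random.Generator
) -> MismatchDistribution:
    """Coalescent sample of n lineages under the two-epoch model, time in
    mutational units (tau-units); mutations Poisson(branch/2) per lineage.
    Returns the mismatch distribution of the simulated sample."""
    # build genealogy
    k = n
    t = 0.0
    active = [frozenset([i]) for i in range(n)]
    branches: list[tuple[frozenset, float]] = []  # (tips below, length)
    birth = {i: 0.0 for i in range(n)}
    node_tips = {i: active[i] for i in range(n)}
    next_id = n
    ids = list(range(n))
    while k > 1:
        theta = theta1 if t < tau else theta0
        if theta <= 0:
            t = max(t, tau)
            theta = theta0 if t >= tau else theta1
            if theta <= 0:
                theta = 1e-6
        rate = k * (k - 1) / 2.0 / theta
        wait = rng.exponential(1.0 / rate)
        if t < tau and t + wait > tau and theta0 != theta1:
            t = tau  # epoch change: redraw in the ancient epoch
            continue
        t += wait
        i, j2 = rng.choice(k, size=2, replace=False)
        a, b = ids[i], ids[j2]
        branches.append((node_tips[a], t - birth[a]))
        branches.append((node_tips[b], t - birth[b]))
        node_tips[next_id] = node_tips[a] | node_tips[b]
        birth[next_id] = t
        ids = [x for x in ids if x not in (a, b)] + [next_id]
        next_id += 1
        k -= 1
    diff = np.zeros((n, n))
    for tips, length in branches:
        muts = rng.poisson(length / 2.0)
        if muts == 0:
            continue
        inside = np.array([i in tips for i in range(n)])
        diff[np.ix_(inside, ~inside)] += muts
    pair_d = []
    for i in range(n - 1):
        for j2 in range(i + 1, n):
            pair_d.append(int(diff[i, j2] + diff[j2, i]))
    counts = np.bincount(np.asarray(pair_d, dtype=int))
    return MismatchDistribution(unit_id="sim", counts=tuple(int(c) for c in counts),
                                n_pairs=len(pair_d))


def goodness_of_fit(
    dist: MismatchDistribution,
    fit: MismatchFit,
    n_bootstrap: int = 200,
    seed: int = 0,
    n_starts: int = 2,
    maxiter: int = 400,
) -> MismatchFit:
    """SSD and raggedness P-values by parametric bootstrap under the fitted
    expansion (same sample size, each replicate refitted)."""
    if n_bootstrap < 1:
        raise MismatchError("n_bootstrap must be >= 1")
    n = int(round((1 + np.sqrt(1 + 8 * dist.n_pairs)) / 2))
    obs_rag = raggedness_index(dist.frequencies)
    rng = np.random.default_rng(seed)
    ssd_ge = 0
    rag_ge = 0
    for b in range(n_bootstrap):
        sim = _simulate_expansion_mismatch(n, fit.tau, fit.theta0, fit.theta1, rng)
        sim_fit = fit_sudden_expansion(sim, n_starts=n_starts, seed=seed + b + 1,
                                       maxiter=maxiter)
        if sim_fit.SSD >= fit.SSD:
            ssd_ge += 1
        if raggedness_index(sim.frequencies) >= obs_rag:
            rag_ge += 1
    return replace(
        fit,
        p_ssd=(ssd_ge + 1) / (n_bootstrap + 1),
        raggedness=obs_rag,
        p_raggedness=(rag_ge + 1) / (n_bootstrap + 1),
        n_bootstrap=n_bootstrap,
    )


# ---------------------------------------------------------------------------
# Shape label
# ---------------------------------------------------------------------------

def classify_profile(
    dist: MismatchDistribution,
    table: HaplotypeTable,
    unit_id: str | None = None,
    smooth_window: int = 3,
    prominence_frac: float = 0.05,
) -> str:
    """Shape label: '1h' (single haplotype), '2h' (exactly two), else 'uni'
    or 'bi' by counting local maxima of the 3-bin moving-average-smoothed
    frequencies with prominence >= 5% of total mass."""
    if unit_id is None:
        h = sum(1 for _, _, c in table.haplotypes if c > 0)
    else:
        h = sum(1 for c in table.counts_for(unit_id).values() if c > 0)
    if h == 1:
        return "1h"
    if h == 2:
        return "2h"
    f = dist.frequencies
    kernel = np.ones(smooth_window) / smooth_window
    smooth = np.convolve(f, kernel, mode="same")
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac)
    return "bi" if len(peaks) >= 2 else "uni"
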