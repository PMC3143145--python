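"""Within-fragment linkage disequilibrium screening.

Because both fragments are short and effectively non-recombining, pairs of
polymorphic sites can be strongly associated, which may bias model-based
clustering.  The screen computes, for every unordered pair of polymorphic
sites, r_LD = |r| of the 2x2 haplotype-count table after dichotomizing each
site into major allele vs rest, and a two-tailed Fisher exact P on the same
table.  Sites involved in at least one pair with P < alpha and
r_LD > threshold (default 0.5) are excluded -- both members of the pair --
to produce the "filtered" dataset variant whose clustering is compared with
the full one as a robustness check.  No multiple-testing correction is
applied; the number of tests is reported so users can correct if desired.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import fisher_exact

from .clustering import compare_clusterings, ConcordanceReport  # noqa: F401  (re-export)
from .seqdata import AlignedDataset, GapMode

__all__ = [
    "LDPair",
    "SiteFilterResult",
    "pairwise_ld",
    "exclude_linked_sites",
    "compare_clusterings",
]


@dataclass(frozen=True)
class LDPair:
    site_a: int  # 1-based alignment column, site_a < site_b
    site_b: int
    r_ld: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class SiteFilterResult:
    excluded_sites: frozenset[int]
    retained_sites: frozenset[int]
    threshold_r: float
    alpha: float
    n_tests: int


def _polymorphic_indicators(
    dataset: AlignedDataset, gap_mode: GapMode
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(column, major-allele indicator, validity mask) per polymorphic site.

    Sites with more than two states are dichotomized major-allele vs rest;
    N is missing; gap is a state only in fifth_state mode.
    """
    gap_mode = GapMode(gap_mode)
    mat = dataset.sequences_array()
    cols = np.arange(1, dataset.alignment_length + 1)
    if gap_mode == GapMode.ignore_gap_columns:
        keep = ~(mat == b"-").any(axis=0)
        mat = mat[:, keep]
        cols = cols[keep]
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        valid = col != b"N"
        if gap_mode != GapMode.fifth_state:
            valid &= col != b"-"
        vals, counts = np.unique(col[valid], return_counts=True)
        if len(vals) < 2:
            continue
        major = vals[counts.argmax()]
        out.append((int(cols[j]), col == major, valid))
    return out


def pairwise_ld(
    dataset: AlignedDataset, gap_mode: GapMode | str = GapMode.fifth_state,
    alpha: float = 0.05,
) -> list[LDPair]:
    """LDPair for every unordered pair of polymorphic sites.

    r_LD = |r| of the 2x2 table of major-vs-other counts; P from the
    two-tailed Fisher exact (hypergeometric) test on the same table.
    Returns an empty list with fewer than two polymorphic sites.
    """
    sites = _polymorphic_indicators(dataset, GapMode(gap_mode))
    pairs: list[LDPair] = []
    for i in range(len(sites) - 1):
        ca, xa, va = sites[i]
        for j in range(i + 1, len(sites)):
            cb, xb, vb = sites[j]
            ok = va & vb
            a = xa[ok]
            b = xb[ok]
            table = np.array(
                [
                    [int((a & b).sum()), int((a & ~b).sum())],
                    [int((~a & b).sum()), int((~a & ~b).sum())],
                ]
            )
            with np.errstate(invalid="ignore"):
                sa, sb = a.std(), b.std()
                r = 0.0 if sa == 0 or sb == 0 else abs(float(np.corrcoef(a, b)[0, 1]))
            p = float(fisher_exact(table, alternative="two-sided")[1])
            pairs.append(LDPair(ca, cb, r, p, bool(p < alpha)))
    return pairs


def exclude_linked_sites(
    pairs: list[LDPair],
    threshold_r: float = 0.5,
    alpha: float = 0.05,
) -> SiteFilterResult:
    """Both members of every pair with P < alpha and r_LD > threshold_r are
    excluded; all other polymorphic sites are retained."""
    all_sites = set()
    excluded = set()
    for p in pairs:
        all_sites.update((p.site_a, p.site_b))
        if p.p_value < alpha and p.r_ld > threshold_r:
            excluded.update((p.site_a, p.site_b))
    return SiteFilterResult(
        excluded_sites=frozenset(excluded),
        retained_sites=frozenset(all_sites - excluded),
        threshold_r=threshold_r,
        alpha=alpha,
        n_tests=len(pairs),
    )
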