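"""Per-isolate synthesis and the genetic-profile (GP1-GP6) classifier.

An isolate's demographic history leaves a joint signature in (i) the ratio
of mitochondrial to nuclear nucleotide diversity, (ii) the absolute pi
values at each locus, (iii) the number of first-level nuclear clusters its
members touch (K_T1), (iv) Tajima's D signs, and (v) the star statistic
S_maj -- the number of segregating sites inside the isolate's majority
(>60%) group of mitochondrial haplotypes lying within two mutational steps
of the most frequent one (a recent-expansion signature).

Six profiles are distinguished:

- GP1  wild condition: two nuclear lineages in a stable hybrid population
       (ratio < 0.5, pi_COI < 0.005, pi_Tpm > 0.0150, K_T1 = 2)
- GP2  farm expansion, three nuclear lineages
       (ratio < 0.5, pi_COI < 0.005, 0.0075 < pi_Tpm < 0.0120, K_T1 = 3)
- GP3  strong founder bottleneck then expansion, two lineages, both D < 0
       (ratio < 0.5, pi_COI < 0.005, 0.0015 < pi_Tpm < 0.0120, K_T1 = 2)
- GP4  very recent secondary contact of divergent maternal lineages
       (ratio > 1.0; the exemplar pi values 0.005/0.0016 are observations,
       not thresholds)
- GP5  secondary contact in a three-lineage background
       (0.5 < ratio < 1.0, 0.005 < pi_COI < 0.020,
       0.0075 < pi_Tpm < 0.0120, K_T1 = 3, D_Tpm > 0)
- GP6  long-isolated sibling lineage (keyed on K_T1 = 1; exemplars
       pi_COI 0.003, pi_Tpm 0.0000)

Rules are evaluated GP6 -> GP4 -> GP5 -> GP1 -> GP2 -> GP3 (cluster-count
and D-sign columns discriminate the overlapping pi ranges); every
comparison is recorded in a trace, and multiple or zero matches yield an
explicit ambiguity rather than a silent label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .clustering import ClusterRun, GenotypeMatrix
from .diversity import DiversitySummary, PiRatioFlag
from .mismatch import MismatchFit
from .seqdata import HaplotypeTable

__all__ = [
    "IsolateSummary",
    "GeneticProfile",
    "GPThresholds",
    "s_maj",
    "k_t1",
    "classify_gp",
]


class ProfileError(ValueError):
    pass


@dataclass(frozen=True)
class IsolateSummary:
    isolate_id: str
    mito: DiversitySummary
    nuc: DiversitySummary
    pi_ratio: PiRatioFlag
    k_t1: int
    s_maj: int | None = None
    majority_lineage: str | None = None
    mismatch_mito: MismatchFit | None = None
    mismatch_nuc: MismatchFit | None = None
    habitat: str | None = None


@dataclass(frozen=True)
class GeneticProfile:
    isolate_id: str
    gp: str | None  # first matching profile, None when nothing matches
    matches: tuple[str, ...]
    ambiguous: bool
    trace: tuple[tuple[str, object, str, bool], ...]  # (criterion, observed, threshold, pass)


@dataclass(frozen=True)
class GPThresholds:
    """User-overridable rule thresholds (defaults transcribed from the
    profile table)."""

    ratio_low: float = 0.5
    ratio_high: float = 1.0
    pi_coi_low: float = 0.005
    pi_coi_gp5: tuple[float, float] = (0.005, 0.020)
    pi_tpm_gp1: float = 0.0150
    pi_tpm_gp2: tuple[float, float] = (0.0075, 0.0120)
    pi_tpm_gp3: tuple[float, float] = (0.0015, 0.0120)
    pi_tpm_gp5: tuple[float, float] = (0.0075, 0.0120)


# ---------------------------------------------------------------------------
# S_maj
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y and x != "N" and y != "N")


def s_maj(table: HaplotypeTable, unit_id: str) -> int | None:
    """Star statistic of the majority mitochondrial haplotype group.

    Center = the unit's most frequent haplotype; group = center plus
    haplotypes within <=2 mutations of it.  When the group carries strictly
    more than 60% of the unit's sequences, returns the number of segregating
    sites among group member sequences; otherwise None (no majority star
    group).
    """
    counts = table.counts_for(unit_id)
    counts = {h: c for h, c in counts.items() if c > 0}
    if not counts:
        raise ProfileError(f"isolate {unit_id!r} empty")
    total = sum(counts.values())
    center = min(counts, key=lambda h: (-counts[h], h))
    cseq = table.sequence_of(center)
    group = [h for h in counts if _hamming(table.sequence_of(h), cseq) <= 2]
    group_n = sum(counts[h] for h in group)
    if group_n / total <= 0.6:
        return None
    seqs = [table.sequence_of(h) for h in group]
    s = 0
    for j in range(len(seqs[0])):
        states = {q[j] for q in seqs} - {"N"}
        if len(states) >= 2:
            s += 1
    return s


# ---------------------------------------------------------------------------
# K_T1
# ---------------------------------------------------------------------------

def k_t1(
    run: ClusterRun,
    isolate_of: Mapping[str, str] | GenotypeMatrix,
    isolate_id: str,
    presence_threshold: float = 0.4,
) -> int:
    """Number of first-level nuclear clusters represented in the isolate.

    A cluster counts when at least one member individual has inferred
    ancestry >= ``presence_threshold`` (0.4 captures both homozygous members
    and the components of inter-cluster heterozygotes).  ``isolate_of`` maps
    individual_id -> isolate_id (a GenotypeMatrix works too).
    """
    if isinstance(isolate_of, GenotypeMatrix):
        isolate_of = dict(zip(isolate_of.individuals, isolate_of.isolates))
    rows = [i for i, ind in enumerate(run.individuals)
            if isolate_of.get(ind) == isolate_id]
    if not rows:
        raise ProfileError(f"isolate {isolate_id!r} absent from clustering run")
    present = (run.Q[rows] >= presence_threshold).any(axis=0)
    return max(int(present.sum()), 1)


# ---------------------------------------------------------------------------
# GP classifier
# ---------------------------------------------------------------------------

def _in_open(x: float | None, lohi: tuple[float, float]) -> bool:
    return x is not None and lohi[0] < x < lohi[1]


def classify_gp(summary: IsolateSummary, thresholds: GPThresholds | None = None) -> GeneticProfile:
    """Rule-cascade classification of an isolate into GP1-GP6.

    Pure function of the summary; every predicate evaluation is recorded in
    the trace.  Isolates matching several profiles (or none) are returned
    with an explicit ambiguity flag.  Missing pi or cluster-count inputs
    raise; an undefined Tajima's D simply fails sign predicates (recorded
    as NA in the trace).
    """
    th = thresholds or GPThresholds()
    for name, val in (("pi_COI", summary.mito.pi), ("pi_Tpm", summary.nuc.pi)):
        if val is None:
            raise ProfileError(f"missing statistic {name} for {summary.isolate_id}")
    if summary.k_t1 is None:
        raise ProfileError(f"missing statistic K_T1 for {summary.isolate_id}")
    ratio = summary.pi_ratio.ratio
    pi_m = summary.mito.pi
    pi_n = summary.nuc.pi
    kt1 = summary.k_t1
    d_m = summary.mito.tajimas_D
    d_n = summary.nuc.tajimas_D

    trace: list[tuple[str, object, str, bool]] = []

    def check(crit: str, observed, threshold_desc: str, ok: bool) -> bool:
        trace.append((crit, observed, threshold_desc, bool(ok)))
        return bool(ok)

    def neg(x):
        return x is not None and x < 0

    def pos(x):
        return x is not None and x > 0

    matches: list[str] = []

    # GP6: keyed on a single first-level nuclear cluster
    if check("GP6: K_T1", kt1, "== 1", kt1 == 1):
        matches.append("GP6")
    # GP4: keyed on mito diversity exceeding nuclear diversity
    if check("GP4: ratio", ratio, f"> {th.ratio_high}",
             ratio is not None and ratio > th.ratio_high) and kt1 != 1:
        matches.append("GP4")
    # GP5
    gp5 = (
        check("GP5: ratio", ratio, f"({th.ratio_low}, {th.ratio_high})",
              ratio is not None and th.ratio_low < ratio < th.ratio_high)
        and check("GP5: pi_COI", pi_m, f"open {th.pi_coi_gp5}", _in_open(pi_m, th.pi_coi_gp5))
        and check("GP5: pi_Tpm", pi_n, f"open {th.pi_tpm_gp5}", _in_open(pi_n, th.pi_tpm_gp5))
        and check("GP5: K_T1", kt1, "== 3", kt1 == 3)
        and check("GP5: D_Tpm", d_n, "> 0", pos(d_n))
    )
    if gp5:
        matches.append("GP5")
    # GP1
    gp1 = (
        check("GP1: ratio", ratio, f"< {th.ratio_low}",
              ratio is not None and ratio < th.ratio_low)
        and check("GP1: pi_COI", pi_m, f"< {th.pi_coi_low}", pi_m < th.pi_coi_low)
        and check("GP1: pi_Tpm", pi_n, f"> {th.pi_tpm_gp1}", pi_n > th.pi_tpm_gp1)
        and check("GP1: K_T1", kt1, "== 2", kt1 == 2)
    )
    if gp1:
        matches.append("GP1")
    # GP2
    gp2 = (
        ratio is not None and ratio < th.ratio_low
        and pi_m < th.pi_coi_low
        and check("GP2: pi_Tpm", pi_n, f"open {th.pi_tpm_gp2}", _in_open(pi_n, th.pi_tpm_gp2))
        and check("GP2: K_T1", kt1, "== 3", kt1 == 3)
    )
    if gp2:
        matches.append("GP2")
    # GP3
    gp3 = (
        ratio is not None and ratio < th.ratio_low
        and pi_m < th.pi_coi_low
        and check("GP3: pi_Tpm", pi_n, f"open {th.pi_tpm_gp3}", _in_open(pi_n, th.pi_tpm_gp3))
        and check("GP3: K_T1", kt1, "== 2", kt1 == 2)
        and check("GP3: D_COI", d_m, "< 0", neg(d_m))
        and check("GP3: D_Tpm", d_n, "< 0", neg(d_n))
    )
    if gp3:
        matches.append("GP3")

    # advisory note on D-sign diversity for the profiles described that way
    diverse = (d_m is None or d_n is None
               or (d_m < 0) != (d_n < 0))
    trace.append(("D values diverse across loci (advisory)",
                  (d_m, d_n), "no consistent sign", diverse))

    gp = matches[0] if matches else None
    return GeneticProfile(
        isolate_id=summary.isolate_id,
        gp=gp,
        matches=tuple(matches),
        ambiguous=len(matches) != 1,
        trace=tuple(trace),
    )
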