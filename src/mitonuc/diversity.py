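"""Per-unit diversity statistics: S, h, Hd, pi, Tajima's D, pi-ratio flag.

pi follows Nei's (1987, eq. 10.5) unbiased per-site nucleotide diversity,
which with sample haplotype frequencies reduces to the mean number of
pairwise differences over all unordered sequence pairs, divided by the
(post gap-handling) alignment length.  Hd carries the n/(n-1) small-sample
correction.  Tajima's (1989) D uses the textbook constants and is reported
as undefined (None), never zero, when S = 0.

The ratio pi_mito/pi_nuclear > 0.5 flags candidate recent secondary contact:
with a 3-fold smaller mitochondrial effective size, a mitochondrial diversity
approaching or exceeding the nuclear one indicates co-occurring divergent
maternal lineages rather than equilibrium variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .seqdata import AlignedDataset, GapMode, HaplotypeTable

__all__ = [
    "DiversitySummary",
    "PiRatioFlag",
    "nucleotide_diversity",
    "haplotype_diversity",
    "tajimas_d",
    "pi_ratio_flag",
    "summarize_unit",
    "pairwise_differences",
]


class DiversityError(ValueError):
    pass


@dataclass(frozen=True)
class DiversitySummary:
    unit_id: str
    locus_name: str
    n_alleles: int
    S: int
    h: int
    Hd: float
    pi: float
    tajimas_D: float | None


@dataclass(frozen=True)
class PiRatioFlag:
    unit_id: str
    ratio: float | None  # pi_mito / pi_nuclear; None when pi_nuclear == 0
    secondary_contact_flag: bool


# ---------------------------------------------------------------------------

def _as_matrix(seqs: Sequence[str]) -> np.ndarray:
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise DiversityError("sequences differ in length")
    return np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)


def _apply_gap_mode(mat: np.ndarray, gap_mode: GapMode) -> np.ndarray:
    gap_mode = GapMode(gap_mode)
    if gap_mode == GapMode.ignore_gap_columns:
        mat = mat[:, ~(mat == b"-").any(axis=0)]
    return mat


def pairwise_differences(seqs: Sequence[str], gap_mode: GapMode | str = GapMode.ignore_gap_columns) -> np.ndarray:
    """Condensed vector of pairwise difference counts over all unordered
    sequence pairs (N always ignored site-wise; gaps per gap_mode)."""
    mat = _apply_gap_mode(_as_matrix(list(seqs)), GapMode(gap_mode))
    n = mat.shape[0]
    out = np.empty(n * (n - 1) // 2, dtype=int)
    k = 0
    valid = mat != b"N"
    for i in range(n - 1):
        diff = (mat[i] != mat[i + 1 :]) & valid[i] & valid[i + 1 :]
        m = n - 1 - i
        out[k : k + m] = diff.sum(axis=1)
        k += m
    return out


def _segregating(mat: np.ndarray, gap_mode: GapMode) -> int:
    s = 0
    for j in range(mat.shape[1]):
        states = set(mat[:, j].tobytes().decode())
        states.discard("N")
        if GapMode(gap_mode) != GapMode.fifth_state:
            states.discard("-")
        if len(states) >= 2:
            s += 1
    return s


def nucleotide_diversity(
    seqs: Sequence[str], gap_mode: GapMode | str = GapMode.ignore_gap_columns
) -> float:
    """Unbiased per-site nucleotide diversity (Nei 1987 eq. 10.5).

    Equals the mean pairwise difference count over unordered sequence pairs
    divided by the alignment length after gap handling (columns with any gap
    removed dataset-wide in ignore_gap_columns mode; gap a fifth state
    otherwise).
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise DiversityError("nucleotide diversity needs >=2 allele sequences")
    mat = _apply_gap_mode(_as_matrix(seqs), GapMode(gap_mode))
    L = mat.shape[1]
    if L == 0:
        return 0.0
    n = mat.shape[0]
    total = 0
    valid = mat != b"N"
    for i in range(n - 1):
        diff = (mat[i] != mat[i + 1 :]) & valid[i] & valid[i + 1 :]
        total += int(diff.sum())
    n_pairs = n * (n - 1) // 2
    return total / n_pairs / L


def haplotype_diversity(table: HaplotypeTable, unit_id: str | None = None) -> tuple[int, float]:
    """(h, Hd) for one isolate (or the whole table when unit_id is None).

    Hd = n/(n-1) * (1 - sum p_i^2) over haplotype frequencies.
    """
    if unit_id is None:
        counts = [c for _, _, c in table.haplotypes]
    else:
        counts = list(table.counts_for(unit_id).values())
    counts = [c for c in counts if c > 0]
    n = sum(counts)
    if n < 2:
        raise DiversityError("haplotype diversity needs >=2 allele sequences")
    p = np.asarray(counts, dtype=float) / n
    hd = n / (n - 1) * (1.0 - float((p**2).sum()))
    return len(counts), hd


_TAJIMA_CACHE: dict[int, tuple[float, float]] = {}


def _tajima_constants(n: int) -> tuple[float, float]:
    if n in _TAJIMA_CACHE:
        return _TAJIMA_CACHE[n]
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    _TAJIMA_CACHE[n] = (e1, e2)
    return e1, e2


def tajimas_d(
    seqs: Sequence[str], gap_mode: GapMode | str = GapMode.ignore_gap_columns
) -> float | None:
    """Tajima's (1989) D; None (undefined) when no segregating sites.

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)) with the standard
    a1, a2, b1, b2, c1, c2, e1, e2 constants; pi_total is the mean pairwise
    difference count (not per site).
    """
    seqs = list(seqs)
    n = len(seqs)
    if n < 2:
        raise DiversityError("Tajima's D needs >=2 allele sequences")
    gap_mode = GapMode(gap_mode)
    mat = _apply_gap_mode(_as_matrix(seqs), gap_mode)
    S = _segregating(mat, gap_mode)
    if S == 0:
        return None
    a1 = sum(1.0 / i for i in range(1, n))
    e1, e2 = _tajima_constants(n)
    d = pairwise_differences(seqs, gap_mode)
    pi_total = float(d.mean())
    denom = np.sqrt(e1 * S + e2 * S * (S - 1))
    return (pi_total - S / a1) / denom


def pi_ratio_flag(mito: DiversitySummary, nuc: DiversitySummary,
                  threshold: float = 0.5) -> PiRatioFlag:
    """Secondary-contact flag: pi_mito/pi_nuclear > threshold (default 0.5).

    Undefined (and never flagged) when the nuclear diversity is zero.
    """
    if mito.unit_id != nuc.unit_id:
        raise DiversityError(
            f"unit mismatch: {mito.unit_id!r} vs {nuc.unit_id!r}"
        )
    if nuc.pi == 0:
        return PiRatioFlag(mito.unit_id, None, False)
    ratio = mito.pi / nuc.pi
    return PiRatioFlag(mito.unit_id, ratio, bool(ratio > threshold))


# ---------------------------------------------------------------------------

def summarize_unit(
    dataset: AlignedDataset,
    unit_id: str,
    gap_mode: GapMode | str = GapMode.ignore_gap_columns,
) -> DiversitySummary:
    """DiversitySummary (n, S, h, Hd, pi, D) for one isolate at one locus."""
    seqs = dataset.sequences_for_isolate(unit_id)
    if len(seqs) < 2:
        raise DiversityError(
            f"isolate {unit_id!r} has {len(seqs)} allele sequence(s) at "
            f"{dataset.locus_name}; need >=2"
        )
    gap_mode = GapMode(gap_mode)
    mat = _apply_gap_mode(_as_matrix(seqs), gap_mode)
    S = _segregating(mat, gap_mode)
    uniq: dict[bytes, int] = {}
    for i in range(mat.shape[0]):
        key = mat[i].tobytes()
        uniq[key] = uniq.get(key, 0) + 1
    n = len(seqs)
    p = np.asarray(list(uniq.values()), dtype=float) / n
    hd = n / (n - 1) * (1.0 - float((p**2).sum()))
    return DiversitySummary(
        unit_id=unit_id,
        locus_name=dataset.locus_name,
        n_alleles=n,
        S=S,
        h=len(uniq),
        Hd=hd,
        pi=nucleotide_diversity(seqs, gap_mode),
        tajimas_D=tajimas_d(seqs, gap_mode),
    )
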