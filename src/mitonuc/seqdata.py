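"""Per-individual aligned sequence data for one locus, plus sample metadata.

Reads and validates the two-locus input format (multi-FASTA with
``>individualID|alleleIndex|isolateID`` headers plus a tab-separated metadata
table), collapses haplotypes under the two gap-handling modes used in the
analysis, and encodes intron indel series as binary presence/absence loci.

Coordinates are 1-based inclusive column intervals throughout, so users can
cross-reference alignment site numbers directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_RESIDUES = frozenset("ACGT-N")
#: metadata column order for the tab-separated sample table
METADATA_COLUMNS = [
    "individual_id",
    "isolate_id",
    "habitat",
    "bird_type",
    "country",
    "region",
    "sampling_point",
]


class GapMode(str, Enum):
    """Gap handling for haplotype collapsing and site counting.

    ``ignore_gap_columns`` removes every column containing a gap dataset-wide
    before comparison (DnaSP-like "gaps unconsidered"), keeping haplotype
    identity transitive.  ``fifth_state`` scores ``-`` as a fifth character
    state.  ``N`` is never counted as a state.
    """

    ignore_gap_columns = "ignore_gap_columns"
    fifth_state = "fifth_state"


class Ploidy(str, Enum):
    haploid = "haploid"
    diploid = "diploid"


class SeqDataError(ValueError):
    """Raised on malformed or inconsistent sequence/metadata input."""


@dataclass(frozen=True)
class SampleRecord:
    individual_id: str
    isolate_id: str
    habitat: str  # "wild" or "domestic"
    bird_type: str = ""
    country: str = ""
    region: str = ""
    sampling_point: str | None = None

    def __post_init__(self):
        if not self.isolate_id:
            raise SeqDataError(f"sample {self.individual_id!r}: empty isolate_id")
        if self.habitat not in ("wild", "domestic"):
            raise SeqDataError(
                f"sample {self.individual_id!r}: habitat must be 'wild' or "
                f"'domestic', got {self.habitat!r}"
            )


@dataclass(frozen=True)
class AlignedDataset:
    """Aligned allele sequences for one locus with per-sample metadata.

    ``sequences`` holds ``(individual_id, allele_index, residues)`` with
    allele_index 0 for the haploid locus and {0, 1} for the diploid one.
    """

    locus_name: str
    ploidy: Ploidy
    alignment_length: int
    sequences: tuple[tuple[str, int, str], ...]
    samples: tuple[SampleRecord, ...]

    def __post_init__(self):
        ids = [s.individual_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SeqDataError(f"duplicate individual_id in metadata: {dup}")
        known = set(ids)
        per_ind: dict[str, list[int]] = {}
        for ind, allele, res in self.sequences:
            if ind not in known:
                raise SeqDataError(f"sequence for {ind!r} has no metadata row")
            if len(res) != self.alignment_length:
                raise SeqDataError(
                    f"sequence {ind!r}/{allele}: length {len(res)} != "
                    f"alignment_length {self.alignment_length}"
                )
            bad = set(res) - VALID_RESIDUES
            if bad:
                raise SeqDataError(
                    f"sequence {ind!r}/{allele}: non-IUPAC characters {sorted(bad)} "
                    "(only A, C, G, T, -, N accepted; ambiguity codes are rejected)"
                )
            per_ind.setdefault(ind, []).append(allele)
        expected = [0] if self.ploidy == Ploidy.haploid else [0, 1]
        for ind in known:
            alleles = sorted(per_ind.get(ind, []))
            if alleles != expected:
                raise SeqDataError(
                    f"individual {ind!r}: {self.ploidy.value} locus requires allele "
                    f"indices {expected}, found {alleles}"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def individuals(self) -> list[str]:
        return [s.individual_id for s in self.samples]

    @property
    def n_alleles_per_individual(self) -> int:
        return 1 if self.ploidy == Ploidy.haploid else 2

    def sample_map(self) -> dict[str, SampleRecord]:
        return {s.individual_id: s for s in self.samples}

    def isolate_of(self, individual_id: str) -> str:
        return self.sample_map()[individual_id].isolate_id

    def sequences_array(self) -> np.ndarray:
        """Residues as a (n_allele_sequences, alignment_length) byte matrix,
        ordered as in ``sequences``."""
        return np.frombuffer(
            "".join(res for _, _, res in self.sequences).encode(), dtype="S1"
        ).reshape(len(self.sequences), self.alignment_length)

    def sequences_for_isolate(self, isolate_id: str) -> list[str]:
        smap = self.sample_map()
        return [
            res
            for ind, _, res in self.sequences
            if smap[ind].isolate_id == isolate_id
        ]

    def subset(self, individual_ids: Iterable[str]) -> "AlignedDataset":
        keep = set(individual_ids)
        missing = keep - set(self.individuals)
        if missing:
            raise SeqDataError(f"unknown individuals in subset: {sorted(missing)}")
        return replace(
            self,
            sequences=tuple(s for s in self.sequences if s[0] in keep),
            samples=tuple(s for s in self.samples if s.individual_id in keep),
        )


@dataclass(frozen=True)
class HaplotypeTable:
    """Distinct haplotypes with counts and per-isolate frequencies."""

    gap_mode: GapMode
    haplotypes: tuple[tuple[str, str, int], ...]  # (haplotype_id, residues, count)
    per_isolate_counts: dict[str, dict[str, int]]
    h: int
    S: int
    #: columns (1-based, original coordinates) retained after gap handling
    retained_columns: tuple[int, ...]

    def counts_for(self, isolate_id: str) -> dict[str, int]:
        if isolate_id not in self.per_isolate_counts:
            raise SeqDataError(f"isolate {isolate_id!r} absent from haplotype table")
        return self.per_isolate_counts[isolate_id]

    def sequence_of(self, haplotype_id: str) -> str:
        for hid, res, _ in self.haplotypes:
            if hid == haplotype_id:
                return res
        raise SeqDataError(f"unknown haplotype {haplotype_id!r}")


@dataclass(frozen=True)
class IndelMatrix:
    """Binary presence/absence matrix over encoded indel series.

    One locus per series: state 1 when any non-gap residue occupies the
    interval, 0 when the interval is all-gap.
    """

    series: tuple[tuple[str, tuple[int, int], tuple[int, ...]], ...]
    n_loci: int
    allele_keys: tuple[tuple[str, int], ...]  # (individual_id, allele_index)
    monomorphic: tuple[str, ...] = field(default_factory=tuple)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_header(header: str) -> tuple[str, int, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise SeqDataError(
            f"FASTA header {header!r} does not follow "
            "'individualID|alleleIndex|isolateID'"
        )
    ind, allele, isolate = parts
    try:
        allele_i = int(allele)
    except ValueError as exc:
        raise SeqDataError(f"non-integer allele index in header {header!r}") from exc
    return ind, allele_i, isolate


def read_metadata(metadata_path: str | Path | io.TextIOBase) -> tuple[SampleRecord, ...]:
    df = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SeqDataError(f"metadata missing columns: {missing_cols}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SampleRecord(
                individual_id=row.individual_id,
                isolate_id=row.isolate_id,
                habitat=row.habitat,
                bird_type=row.bird_type,
                country=row.country,
                region=row.region,
                sampling_point=row.sampling_point or None,
            )
        )
    return tuple(records)


def read_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path,
    ploidy: Ploidy | str,
    locus_name: str | None = None,
) -> AlignedDataset:
    """Read one locus from multi-FASTA + metadata and validate it.

    FASTA headers must follow ``individualID|alleleIndex|isolateID``; the
    isolate in the header must agree with the metadata table.
    """
    ploidy = Ploidy(ploidy)
    samples = read_metadata(metadata_path)
    smap = {s.individual_id: s for s in samples}
    sequences: list[tuple[str, int, str]] = []
    length = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        ind, allele, isolate = _parse_header(rec.id)
        if ind not in smap:
            raise SeqDataError(f"missing metadata row for individual {ind!r}")
        if smap[ind].isolate_id != isolate:
            raise SeqDataError(
                f"individual {ind!r}: header isolate {isolate!r} disagrees with "
                f"metadata isolate {smap[ind].isolate_id!r}"
            )
        res = str(rec.seq).upper()
        if length is None:
            length = len(res)
        sequences.append((ind, allele, res))
    if not sequences:
        raise SeqDataError(f"no sequences in {fasta_path}")
    # restrict metadata to individuals present in this locus (metadata may
    # cover the union of both loci)
    present = {ind for ind, _, _ in sequences}
    samples_here = tuple(s for s in samples if s.individual_id in present)
    return AlignedDataset(
        locus_name=locus_name or Path(str(fasta_path)).stem,
        ploidy=ploidy,
        alignment_length=length,
        sequences=tuple(sequences),
        samples=samples_here,
    )


def write_alignment(dataset: AlignedDataset, fasta_path: str | Path,
                    metadata_path: str | Path | None = None) -> None:
    """Write a dataset back to the FASTA + metadata dialect read_alignment expects."""
    smap = dataset.sample_map()
    records = [
        SeqRecord(Seq(res), id=f"{ind}|{allele}|{smap[ind].isolate_id}", description="")
        for ind, allele, res in dataset.sequences
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")
    if metadata_path is not None:
        write_metadata(dataset.samples, metadata_path)


def write_metadata(samples: Sequence[SampleRecord], metadata_path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "isolate_id": s.isolate_id,
                "habitat": s.habitat,
                "bird_type": s.bird_type,
                "country": s.country,
                "region": s.region,
                "sampling_point": s.sampling_point or "",
            }
            for s in samples
        ],
        columns=METADATA_COLUMNS,
    )
    df.to_csv(metadata_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

def _normalized_matrix(dataset: AlignedDataset, gap_mode: GapMode) -> tuple[np.ndarray, np.ndarray]:
    """Return (byte matrix after gap handling, retained original 1-based columns)."""
    mat = dataset.sequences_array()
    cols = np.arange(1, dataset.alignment_length + 1)
    if gap_mode == GapMode.ignore_gap_columns:
        keep = ~(mat == b"-").any(axis=0)
        mat = mat[:, keep]
        cols = cols[keep]
    return mat, cols


def segregating_sites(mat: np.ndarray, gap_mode: GapMode) -> int:
    """Number of columns with >=2 observed states.

    Gap counts as a state only in fifth_state mode (in ignore_gap_columns mode
    gap columns have already been removed); N never counts as a state.
    """
    s = 0
    for j in range(mat.shape[1]):
        col = mat[:, j]
        states = set(col.tobytes().decode())
        states.discard("N")
        if gap_mode != GapMode.fifth_state:
            states.discard("-")
        if len(states) >= 2:
            s += 1
    return s


def collapse_haplotypes(dataset: AlignedDataset, gap_mode: GapMode | str) -> HaplotypeTable:
    """Collapse identical allele sequences (after gap-mode normalization).

    Haplotype ids are assigned in decreasing order of total count
    (ties broken lexicographically by sequence) so that relabeling is
    deterministic and order-independent.
    """
    gap_mode = GapMode(gap_mode)
    if not dataset.sequences:
        raise SeqDataError("cannot collapse an empty dataset")
    mat, cols = _normalized_matrix(dataset, gap_mode)
    smap = dataset.sample_map()
    seq_strings = [mat[i].tobytes().decode() for i in range(mat.shape[0])]
    counts: dict[str, int] = {}
    per_isolate: dict[str, dict[str, int]] = {}
    for (ind, _, _), seq in zip(dataset.sequences, seq_strings):
        counts[seq] = counts.get(seq, 0) + 1
    order = sorted(counts, key=lambda s: (-counts[s], s))
    hap_id = {seq: f"H{i + 1}" for i, seq in enumerate(order)}
    for (ind, _, _), seq in zip(dataset.sequences, seq_strings):
        iso = smap[ind].isolate_id
        per_isolate.setdefault(iso, {})
        hid = hap_id[seq]
        per_isolate[iso][hid] = per_isolate[iso].get(hid, 0) + 1
    S = segregating_sites(mat, gap_mode)
    return HaplotypeTable(
        gap_mode=gap_mode,
        haplotypes=tuple((hap_id[s], s, counts[s]) for s in order),
        per_isolate_counts=per_isolate,
        h=len(order),
        S=S,
        retained_columns=tuple(int(c) for c in cols),
    )


# ---------------------------------------------------------------------------
# Indel series encoding
# ---------------------------------------------------------------------------

def encode_indel_series(
    dataset: AlignedDataset,
    series_intervals: Sequence[tuple[int, int]],
) -> IndelMatrix:
    """Encode each indel series as one binary presence/absence locus.

    ``series_intervals`` are 1-based inclusive ``(start, end)`` column
    intervals; they must be non-overlapping and lie within the alignment.
    State 1 = any non-gap residue in the interval, 0 = all-gap.
    """
    ivs = sorted(series_intervals)
    for (a, b) in ivs:
        if a < 1 or b > dataset.alignment_length or a > b:
            raise SeqDataError(
                f"interval [{a},{b}] outside alignment 1..{dataset.alignment_length}"
            )
    for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
        if a2 <= b1:
            raise SeqDataError(f"overlapping intervals [{a1},{b1}] and [{a2},{b2}]")
    mat = dataset.sequences_array()
    keys = tuple((ind, allele) for ind, allele, _ in dataset.sequences)
    series = []
    monomorphic = []
    for i, (a, b) in enumerate(series_intervals):
        block = mat[:, a - 1 : b]
        states = tuple(int((row != b"-").any()) for row in block)
        sid = f"indel_{i + 1}"
        series.append((sid, (a, b), states))
        if len(set(states)) == 1:
            monomorphic.append(sid)
    return IndelMatrix(
        series=tuple(series),
        n_loci=len(series),
        allele_keys=keys,
        monomorphic=tuple(monomorphic),
    )


def detect_indel_series(dataset: AlignedDataset, min_len: int = 1) -> list[tuple[int, int]]:
    """Heuristic convenience: maximal runs of columns in which gap presence is
    identical across sequences and at least one sequence is gapped."""
    mat = dataset.sequences_array() == b"-"
    if not mat.any():
        return []
    n, L = mat.shape
    runs: list[tuple[int, int]] = []
    start = None
    prev_col = None
    for j in range(L):
        col = mat[:, j]
        if col.any():
            if start is not None and prev_col is not None and (col == prev_col).all():
                pass
            else:
                if start is not None:
                    runs.append((start + 1, j))
                start = j
            prev_col = col
        else:
            if start is not None:
                runs.append((start + 1, j))
                start = None
                prev_col = None
    if start is not None:
        runs.append((start + 1, L))
    return [(a, b) for a, b in runs if b - a + 1 >= min_len]
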