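"""Structured-coalescent generator for mito-nuclear scenarios with truth labels.

Simulates linked haploid mitochondrial (maternal) and diploid nuclear loci for
demographic scenarios built from demes, splits, admixture pulses and
bottlenecks, under haplodiploid or diplodiploid inheritance.  Per-genome
effective copy numbers follow the inheritance system:

- haplodiploid: nuclear gene copies ``2*N_f + N_m``, mitochondrial ``N_f``
- diplodiploid: nuclear ``2*(N_f + N_m)``, mitochondrial ``N_f``

so a single deme with equal sex numbers carries a 3-fold (haplodiploid) or
4-fold (diplodiploid) nuclear/mito effective-size ratio.

The engine is a discrete-event structured coalescent (exponential waiting
times within demes, pastward-ordered demographic events), with infinite-sites
substitutions (collision re-draw on the finite alignment) and a two-state
toggle process for intron indel series.  Time is measured in generations,
sizes in individuals.

Scenario construction knobs, notably ``mito_proportions`` on admixture pulses
and per-individual ``father_deme`` in the sampling plan, allow maternally
biased founding (mitochondria fixed for one source lineage inside a nuclear
hybrid swarm) and structured F1 crosses (one nuclear allele from each parent
deme), the two ingredients of the mito-nuclear discordance patterns under
study.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import AlignedDataset, Ploidy, SampleRecord

BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scenario description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Deme:
    id: str
    N_f: int
    N_m: int

    def __post_init__(self):
        if self.N_f < 0 or self.N_m < 0:
            raise ScenarioError(f"deme {self.id}: negative size")


@dataclass(frozen=True)
class Split:
    """Pastward at ``time``, lineages of ``child`` move into ``parent``."""
    time: float
    parent: str
    child: str


@dataclass(frozen=True)
class AdmixturePulse:
    """Pastward at ``time``, each lineage in ``target`` is reassigned to
    ``sources[i]`` with probability ``proportions[i]``.

    ``proportions`` route nuclear lineages; ``mito_proportions`` (default:
    same) route mitochondrial lineages, allowing maternally biased founding.
    A pulse with proportions summing to 1 empties the target pastward and so
    also models the founding of a new deme.
    """
    time: float
    target: str
    sources: tuple[str, ...]
    proportions: tuple[float, ...]
    mito_proportions: tuple[float, ...] | None = None

    def __post_init__(self):
        if len(self.sources) != len(self.proportions):
            raise ScenarioError("pulse: sources and proportions differ in length")
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ScenarioError("pulse: proportions must sum to 1")
        if self.mito_proportions is not None and abs(sum(self.mito_proportions) - 1.0) > 1e-9:
            raise ScenarioError("pulse: mito_proportions must sum to 1")


@dataclass(frozen=True)
class SizeChange:
    """Pastward of ``time`` the deme has sizes (N_f, N_m)."""
    time: float
    deme: str
    N_f: int
    N_m: int


@dataclass(frozen=True)
class Bottleneck:
    """Forward story: the deme had sizes (N_f, N_m) between ``time`` and
    ``time + duration`` generations ago, and its declared (current) sizes
    more recently.  Expands to two SizeChange events."""
    time: float
    deme: str
    N_f: int
    N_m: int
    duration: float

    def expand(self, current: Deme) -> list[SizeChange]:
        return [
            SizeChange(self.time, self.deme, self.N_f, self.N_m),
            SizeChange(self.time + self.duration, self.deme, current.N_f, current.N_m),
        ]


@dataclass(frozen=True)
class SampleSpec:
    """Sample ``n`` individuals from ``deme`` under isolate label ``isolate``.

    ``father_deme`` (diploid locus only) places each individual's second
    nuclear allele in a different deme, producing structured F1 hybrids; the
    mitochondrion always follows the maternal deme (= ``deme``).
    """
    deme: str
    n: int
    isolate: str
    habitat: str = "domestic"
    bird_type: str = ""
    country: str = ""
    region: str = ""
    father_deme: str | None = None


@dataclass(frozen=True)
class SimScenario:
    name: str
    inheritance: str  # "haplodiploid" | "diplodiploid"
    demes: tuple[Deme, ...]
    events: tuple = ()
    sampling: tuple[SampleSpec, ...] = ()
    mito_length: int = 543
    mito_mu: float = 5e-6  # per site per generation
    nuc_length: int = 729
    nuc_mu: float = 1e-6
    indel_series: tuple[tuple[int, int], ...] = ()
    indel_rate: float = 0.0  # toggle rate per series per generation
    ancestry_time: float = 0.0  # snapshot time defining ancestral-lineage labels
    seed: int = 0
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.inheritance not in ("haplodiploid", "diplodiploid"):
            raise ScenarioError(f"unknown inheritance {self.inheritance!r}")
        times = [e.time for e in self.events]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScenarioError("event times must be strictly increasing pastward")
        ids = [d.id for d in self.demes]
        if len(set(ids)) != len(ids):
            raise ScenarioError("duplicate deme ids")

    def deme_map(self) -> dict[str, Deme]:
        return {d.id: d for d in self.demes}


def nuclear_copies(N_f: int, N_m: int, inheritance: str) -> int:
    return 2 * N_f + N_m if inheritance == "haplodiploid" else 2 * (N_f + N_m)


def mito_copies(N_f: int, N_m: int, inheritance: str) -> int:
    return N_f


def expected_ne_ratio(scenario: SimScenario) -> float:
    """Nuclear-copies / mito-copies ratio for a single-deme scenario:
    (2N_f+N_m)/N_f haplodiploid, 2(N_f+N_m)/N_f diplodiploid."""
    if len(scenario.demes) != 1:
        raise ScenarioError("expected_ne_ratio is defined for single-deme scenarios")
    d = scenario.demes[0]
    if d.N_f == 0:
        raise ScenarioError("N_f = 0: mitochondrial effective size undefined")
    return nuclear_copies(d.N_f, d.N_m, scenario.inheritance) / mito_copies(
        d.N_f, d.N_m, scenario.inheritance
    )


# ---------------------------------------------------------------------------
# Truth labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndividualTruth:
    individual_id: str
    deme: str
    isolate: str
    ancestry: dict[str, float]  # ancestral-lineage label -> nuclear fraction
    mito_lineage: str
    hybrid_class: str  # unadmixed | F1 | swarm
    father_deme: str | None = None


@dataclass(frozen=True)
class SimTruth:
    individuals: tuple[IndividualTruth, ...]
    nuclear_copies_per_deme: dict[str, int]
    mito_copies_per_deme: dict[str, int]
    scenario_name: str
    meta: dict = field(default_factory=dict)

    def by_id(self) -> dict[str, IndividualTruth]:
        return {t.individual_id: t for t in self.individuals}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "scenario": self.scenario_name,
            "meta": self.meta,
            "nuclear_copies_per_deme": self.nuclear_copies_per_deme,
            "mito_copies_per_deme": self.mito_copies_per_deme,
            "individuals": [
                {
                    "individual_id": t.individual_id,
                    "deme": t.deme,
                    "isolate": t.isolate,
                    "ancestry": t.ancestry,
                    "mito_lineage": t.mito_lineage,
                    "hybrid_class": t.hybrid_class,
                    "father_deme": t.father_deme,
                }
                for t in self.individuals
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Coalescent engine
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("node", "deme", "tips")

    def __init__(self, node: int, deme: str, tips: frozenset[int]):
        self.node = node
        self.deme = deme
        self.tips = tips


def _copies_fn(scenario: SimScenario, locus: str):
    if locus == "mito":
        return lambda N_f, N_m: mito_copies(N_f, N_m, scenario.inheritance)
    return lambda N_f, N_m: nuclear_copies(N_f, N_m, scenario.inheritance)


def _simulate_tree(
    scenario: SimScenario,
    tip_demes: Sequence[str],
    locus: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, dict[int, str]]:
    """Coalesce ``tip_demes`` under the scenario.

    Returns (parent array, node time array, tip ancestry-label map).
    Node 0..n-1 are tips; the root has parent -1.
    """
    copies = _copies_fn(scenario, locus)
    sizes = {d.id: (d.N_f, d.N_m) for d in scenario.demes}
    n = len(tip_demes)
    parent = [-1] * n
    time_of = [0.0] * n
    lineages = [_Lineage(i, d, frozenset([i])) for i, d in enumerate(tip_demes)]

    events: list = []
    for ev in scenario.events:
        if isinstance(ev, Bottleneck):
            events.extend(ev.expand(scenario.deme_map()[ev.deme]))
        else:
            events.append(ev)
    events.sort(key=lambda e: e.time)
    snapshot_done = scenario.ancestry_time <= 0.0
    ancestry: dict[int, str] = {}
    if snapshot_done:
        ancestry = {i: d for i, d in enumerate(tip_demes)}

    t = 0.0
    ev_i = 0
    guard = 0
    while len(lineages) > 1:
        guard += 1
        if guard > 10_000_000:
            raise ScenarioError("coalescent did not terminate (check scenario)")
        by_deme: dict[str, list[_Lineage]] = {}
        for lin in lineages:
            by_deme.setdefault(lin.deme, []).append(lin)
        rates = {}
        for d, lins in by_deme.items():
            k = len(lins)
            if k >= 2:
                N = copies(*sizes[d])
                if N <= 0:
                    raise ScenarioError(f"deme {d}: zero copies with lineages present")
                rates[d] = k * (k - 1) / 2.0 / N
        total = sum(rates.values())
        t_next_event = events[ev_i].time if ev_i < len(events) else np.inf
        t_snap = scenario.ancestry_time if not snapshot_done else np.inf
        horizon = min(t_next_event, t_snap)
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if t + wait < horizon:
            t += wait
            ds = list(rates)
            probs = np.array([rates[d] for d in ds]) / total
            d = ds[rng.choice(len(ds), p=probs)]
            pair = rng.choice(len(by_deme[d]), size=2, replace=False)
            l1, l2 = by_deme[d][pair[0]], by_deme[d][pair[1]]
            node = len(parent)
            parent.append(-1)
            time_of.append(t)
            parent[l1.node] = node
            parent[l2.node] = node
            merged = _Lineage(node, d, l1.tips | l2.tips)
            lineages = [l for l in lineages if l is not l1 and l is not l2]
            lineages.append(merged)
        elif horizon == np.inf:
            raise ScenarioError(
                "lineages remain in disconnected demes with no further events"
            )
        elif not snapshot_done and t_snap <= t_next_event:
            t = t_snap
            for lin in lineages:
                for tip in lin.tips:
                    ancestry[tip] = lin.deme
            snapshot_done = True
        else:
            ev = events[ev_i]
            ev_i += 1
            t = ev.time
            if isinstance(ev, SizeChange):
                sizes[ev.deme] = (ev.N_f, ev.N_m)
            elif isinstance(ev, Split):
                for lin in lineages:
                    if lin.deme == ev.child:
                        lin.deme = ev.parent
            elif isinstance(ev, AdmixturePulse):
                props = ev.proportions
                if locus == "mito" and ev.mito_proportions is not None:
                    props = ev.mito_proportions
                p = np.asarray(props, dtype=float)
                for lin in lineages:
                    if lin.deme == ev.target:
                        lin.deme = ev.sources[rng.choice(len(ev.sources), p=p)]
            else:  # pragma: no cover - validated earlier
                raise ScenarioError(f"unknown event {ev!r}")
    if not snapshot_done:
        root = lineages[0]
        for tip in root.tips:
            ancestry[tip] = root.deme
    return np.asarray(parent), np.asarray(time_of), ancestry


def _mutate_on_tree(
    parent: np.ndarray,
    time_of: np.ndarray,
    length: int,
    mu: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Infinite-sites substitutions with collision re-draw.

    Returns a (n_nodes, length) byte matrix of sequences; tips are rows
    0..n_tips-1."""
    n_nodes = len(parent)
    root = int(np.where(parent == -1)[0][0])
    ancestral = BASES[rng.integers(0, 4, size=length)]
    used: set[int] = set()
    branch_muts: dict[int, list[tuple[int, bytes]]] = {}
    for node in range(n_nodes):
        if node == root:
            continue
        ell = time_of[parent[node]] - time_of[node]
        k = rng.poisson(mu * length * ell)
        muts = []
        for _ in range(k):
            for _try in range(1000):
                site = int(rng.integers(0, length))
                if site not in used:
                    used.add(site)
                    break
            else:
                raise ScenarioError(
                    "alignment saturated: mutation count approaches length; "
                    "lower the mutation rate or shorten the scenario"
                )
            anc = ancestral[site]
            alts = BASES[BASES != anc]
            muts.append((site, alts[rng.integers(0, 3)]))
        branch_muts[node] = muts
    seqs = np.empty((n_nodes, length), dtype="S1")
    # children lists for top-down traversal
    children: dict[int, list[int]] = {}
    for node in range(n_nodes):
        if parent[node] >= 0:
            children.setdefault(int(parent[node]), []).append(node)
    stack = [root]
    seqs[root] = ancestral
    while stack:
        node = stack.pop()
        for ch in children.get(node, []):
            s = seqs[node].copy()
            for site, base in branch_muts[ch]:
                s[site] = base
            seqs[ch] = s
            stack.append(ch)
    return seqs


def _indel_states(
    parent: np.ndarray,
    time_of: np.ndarray,
    n_series: int,
    rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-state toggle process per series; root state = present (1).
    Returns (n_tips_implied_by_caller, n_series) bool via full node matrix."""
    n_nodes = len(parent)
    root = int(np.where(parent == -1)[0][0])
    states = np.ones((n_nodes, n_series), dtype=int)
    children: dict[int, list[int]] = {}
    for node in range(n_nodes):
        if parent[node] >= 0:
            children.setdefault(int(parent[node]), []).append(node)
    stack = [root]
    while stack:
        node = stack.pop()
        for ch in children.get(node, []):
            ell = time_of[node] - time_of[ch]
            flips = rng.poisson(rate * ell, size=n_series) % 2
            states[ch] = states[node] ^ flips
            stack.append(ch)
    return states


# ---------------------------------------------------------------------------
# Scenario simulation
# ---------------------------------------------------------------------------

def simulate(
    scenario: SimScenario, seed: int | None = None
) -> tuple[AlignedDataset, AlignedDataset, SimTruth]:
    """Simulate one mito + one nuclear AlignedDataset with truth labels.

    Byte-identical output for identical (scenario, seed).
    """
    seed = scenario.seed if seed is None else seed
    dmap = scenario.deme_map()
    for spec in scenario.sampling:
        if spec.deme not in dmap:
            raise ScenarioError(f"sampling from unknown deme {spec.deme!r}")
        if spec.n > dmap[spec.deme].N_f:
            raise ScenarioError(
                f"sampling {spec.n} females from deme {spec.deme} exceeds N_f="
                f"{dmap[spec.deme].N_f}"
            )
        if spec.father_deme is not None and spec.father_deme not in dmap:
            raise ScenarioError(f"unknown father_deme {spec.father_deme!r}")
    individuals: list[tuple[str, SampleSpec]] = []
    counter = 0
    for spec in scenario.sampling:
        for _ in range(spec.n):
            counter += 1
            individuals.append((f"i{counter:03d}", spec))
    if not individuals:
        raise ScenarioError("empty sampling plan")

    # tip demes per locus
    mito_tips = [spec.deme for _, spec in individuals]
    nuc_tips: list[str] = []
    for _, spec in individuals:
        nuc_tips.append(spec.deme)  # maternal allele
        nuc_tips.append(spec.father_deme or spec.deme)  # paternal allele

    rng_m = np.random.default_rng([seed, 11])
    rng_n = np.random.default_rng([seed, 13])

    par_m, t_m, anc_m = _simulate_tree(scenario, mito_tips, "mito", rng_m)
    seqs_m = _mutate_on_tree(par_m, t_m, scenario.mito_length, scenario.mito_mu, rng_m)

    par_n, t_n, anc_n = _simulate_tree(scenario, nuc_tips, "nuclear", rng_n)
    seqs_n = _mutate_on_tree(par_n, t_n, scenario.nuc_length, scenario.nuc_mu, rng_n)
    if scenario.indel_series:
        states = _indel_states(
            par_n, t_n, len(scenario.indel_series), scenario.indel_rate, rng_n
        )
        for tip in range(len(nuc_tips)):
            for s_i, (a, b) in enumerate(scenario.indel_series):
                if states[tip, s_i] == 0:
                    seqs_n[tip, a - 1 : b] = b"-"

    samples = tuple(
        SampleRecord(
            individual_id=ind,
            isolate_id=spec.isolate,
            habitat=spec.habitat,
            bird_type=spec.bird_type,
            country=spec.country,
            region=spec.region,
        )
        for ind, spec in individuals
    )
    mito_seqs = tuple(
        (ind, 0, seqs_m[i].tobytes().decode())
        for i, (ind, _) in enumerate(individuals)
    )
    nuc_seqs = []
    for i, (ind, _) in enumerate(individuals):
        nuc_seqs.append((ind, 0, seqs_n[2 * i].tobytes().decode()))
        nuc_seqs.append((ind, 1, seqs_n[2 * i + 1].tobytes().decode()))
    mito_ds = AlignedDataset(
        locus_name="mito",
        ploidy=Ploidy.haploid,
        alignment_length=scenario.mito_length,
        sequences=mito_seqs,
        samples=samples,
    )
    nuc_ds = AlignedDataset(
        locus_name="nuclear",
        ploidy=Ploidy.diploid,
        alignment_length=scenario.nuc_length,
        sequences=tuple(nuc_seqs),
        samples=samples,
    )

    truths = []
    for i, (ind, spec) in enumerate(individuals):
        labels = [anc_n[2 * i], anc_n[2 * i + 1]]
        ancestry: dict[str, float] = {}
        for lab in labels:
            ancestry[lab] = ancestry.get(lab, 0.0) + 0.5
        if spec.father_deme is not None and len(ancestry) > 1:
            hclass = "F1"
        elif len(ancestry) > 1:
            hclass = "swarm"
        else:
            hclass = "unadmixed"
        truths.append(
            IndividualTruth(
                individual_id=ind,
                deme=spec.deme,
                isolate=spec.isolate,
                ancestry=ancestry,
                mito_lineage=anc_m[i],
                hybrid_class=hclass,
                father_deme=spec.father_deme,
            )
        )
    truth = SimTruth(
        individuals=tuple(truths),
        nuclear_copies_per_deme={
            d.id: nuclear_copies(d.N_f, d.N_m, scenario.inheritance)
            for d in scenario.demes
        },
        mito_copies_per_deme={d.id: d.N_f for d in scenario.demes},
        scenario_name=scenario.name,
        meta=dict(scenario.meta),
    )
    return mito_ds, nuc_ds, truth


# ---------------------------------------------------------------------------
# Convenience scenario builders
# ---------------------------------------------------------------------------

def single_deme_scenario(
    N_f: int = 500,
    N_m: int = 500,
    inheritance: str = "haplodiploid",
    n: int = 20,
    mu: float = 1e-5,
    seed: int = 0,
    isolate: str = "ISO1",
) -> SimScenario:
    """Neutral single-deme scenario with equal per-site mutation rates for
    both loci; the basis of the effective-size-ratio calibration."""
    return SimScenario(
        name="single_deme",
        inheritance=inheritance,
        demes=(Deme("P", N_f, N_m),),
        sampling=(SampleSpec("P", n, isolate),),
        mito_mu=mu,
        nuc_mu=mu,
        seed=seed,
    )


def two_population_scenario(
    split_time: float = 3000.0,
    N_f: int = 250,
    N_m: int = 250,
    n_per_pop: int = 15,
    n_f1: int = 0,
    mu_mito: float = 5e-6,
    mu_nuc: float = 2e-6,
    seed: int = 0,
) -> SimScenario:
    """Two demes split ``split_time`` generations ago, optional structured F1
    hybrids (mother from A, father from B)."""
    sampling = [
        SampleSpec("A", n_per_pop, "POPA"),
        SampleSpec("B", n_per_pop, "POPB"),
    ]
    if n_f1:
        sampling.append(SampleSpec("A", n_f1, "HYB", father_deme="B"))
    return SimScenario(
        name="two_pop",
        inheritance="haplodiploid",
        demes=(Deme("anc", N_f, N_m), Deme("A", N_f, N_m), Deme("B", N_f, N_m)),
        events=(Split(split_time, "anc", "A"), Split(split_time + 1, "anc", "B")),
        sampling=tuple(sampling),
        mito_mu=mu_mito,
        nuc_mu=mu_nuc,
        seed=seed,
    )


_INDEL_SERIES_8 = (
    (101, 108), (168, 176), (241, 246), (312, 323),
    (402, 408), (473, 481), (547, 556), (631, 638),
)


def _radiation(names: Sequence[str], t0: float, anc: str = "anc") -> tuple[Split, ...]:
    return tuple(Split(t0 + i, anc, nm) for i, nm in enumerate(names))


def scripted_scenarios() -> list[SimScenario]:
    """The scripted demographic scenarios whose summary-statistic signatures
    correspond to the six genetic profiles, plus a motley-farm scenario.

    Each scenario samples one target isolate and pure-lineage anchor isolates;
    anchors pin down the first-level nuclear clustering against which the
    target's cluster count is read (the cluster analysis is run on the whole
    sample, as in a multi-isolate study, not per isolate).  ``meta`` records
    the intended profile and the target isolate.
    """
    scenarios: list[SimScenario] = []

    # GP1: wild condition -- ancient two-lineage nuclear hybrid swarm with
    # maternally sorted mitochondria, large stable deme.
    scenarios.append(SimScenario(
        name="wild_two_lineage_swarm",
        inheritance="haplodiploid",
        demes=(Deme("anc", 150, 150), Deme("A", 150, 150), Deme("B", 150, 150),
               Deme("W", 1000, 1000)),
        events=(
            AdmixturePulse(30.0, "W", ("A", "B"), (0.5, 0.5),
                           mito_proportions=(1.0, 0.0)),
        ) + _radiation(["A", "B"], 26000.0),
        sampling=(
            SampleSpec("W", 20, "WILD", habitat="wild", bird_type="starling"),
            SampleSpec("A", 10, "ANC_A"),
            SampleSpec("B", 10, "ANC_B"),
        ),
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=50.0,
        meta={"intended_gp": "GP1", "target_isolate": "WILD", "expected_k1": 2},
    ))

    # GP2: farm isolate dominated by lineage A with a few recent paternal
    # immigrants from deeply divergent lineages B and C (three first-level
    # clusters).  The deterministic immigrant counts put the between-lineage
    # divergence on ~55 deep mutations, which is what keeps pi_Tpm stable
    # inside its narrow profile window at a 729-bp scale; anchor isolates are
    # sized to balance the three clusters for the deltaK model choice.
    scenarios.append(SimScenario(
        name="farm_three_cluster_contact",
        inheritance="haplodiploid",
        demes=(Deme("anc", 40, 40), Deme("A", 40, 40), Deme("B", 40, 40),
               Deme("C", 40, 40)),
        events=_radiation(["A", "B", "C"], 25000.0),
        sampling=(
            SampleSpec("A", 16, "FARM", bird_type="layer"),
            SampleSpec("A", 2, "FARM", bird_type="layer", father_deme="B"),
            SampleSpec("A", 2, "FARM", bird_type="layer", father_deme="C"),
            SampleSpec("A", 6, "ANC_A"),
            SampleSpec("B", 20, "ANC_B"),
            SampleSpec("C", 20, "ANC_C"),
        ),
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=100.0,
        meta={"intended_gp": "GP2", "target_isolate": "FARM", "expected_k1": 3},
    ))

    # GP3: farm founded through a strong bottleneck then expansion, with a
    # few recent paternal immigrants from a second lineage.
    scenarios.append(SimScenario(
        name="farm_bottleneck_expansion",
        inheritance="haplodiploid",
        demes=(Deme("anc", 150, 150), Deme("A", 400, 400), Deme("B", 150, 150),
               Deme("F", 2000, 2000)),
        events=(
            SizeChange(120.0, "F", 2, 2),
            AdmixturePulse(132.0, "F", ("A",), (1.0,)),
        ) + _radiation(["A", "B"], 12000.0),
        sampling=(
            SampleSpec("F", 15, "FARM", bird_type="layer"),
            SampleSpec("F", 5, "FARM", bird_type="layer", father_deme="B"),
            SampleSpec("A", 10, "ANC_A"),
            SampleSpec("B", 10, "ANC_B"),
        ),
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=200.0,
        meta={"intended_gp": "GP3", "target_isolate": "FARM", "expected_k1": 2},
    ))

    # GP4: very recent secondary contact of mito-divergent farms (motley at
    # low minority frequency): high pi_COI/pi_Tpm ratio, negative D.
    scenarios.append(SimScenario(
        name="recent_contact_high_ratio",
        inheritance="haplodiploid",
        demes=(Deme("anc", 150, 150), Deme("A", 150, 150), Deme("B", 150, 150),
               Deme("FA", 400, 400), Deme("FB", 400, 400)),
        events=(
            SizeChange(80.0, "FA", 10, 10),
            SizeChange(81.0, "FB", 10, 10),
            AdmixturePulse(130.0, "FA", ("A",), (1.0,)),
            AdmixturePulse(132.0, "FB", ("B",), (1.0,)),
        ) + _radiation(["A", "B"], 12000.0),
        sampling=(
            SampleSpec("FA", 18, "FARM", bird_type="layer"),
            SampleSpec("FB", 2, "FARM", bird_type="layer"),
            SampleSpec("A", 10, "ANC_A"),
            SampleSpec("B", 10, "ANC_B"),
        ),
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=200.0,
        meta={"intended_gp": "GP4", "target_isolate": "FARM", "expected_k1": 2},
    ))

    # GP5: recent secondary contact in a three-lineage background --
    # heterozygous paternal immigrants from lineages B and C at intermediate
    # frequency (balanced divergent alleles push D_Tpm positive) plus two
    # immigrant females carrying a second mitochondrial lineage
    # (intermediate pi_COI/pi_Tpm ratio).  Source demes are kept tiny so the
    # segregating variation is almost purely the between-lineage divergence.
    scenarios.append(SimScenario(
        name="recent_secondary_contact",
        inheritance="haplodiploid",
        demes=(Deme("anc", 20, 20), Deme("A", 20, 20), Deme("B", 20, 20),
               Deme("C", 20, 20)),
        events=_radiation(["A", "B", "C"], 7750.0),
        sampling=(
            SampleSpec("A", 6, "FARM", bird_type="broiler"),
            SampleSpec("B", 2, "FARM", bird_type="broiler"),
            SampleSpec("A", 6, "FARM", bird_type="broiler", father_deme="B"),
            SampleSpec("A", 6, "FARM", bird_type="broiler", father_deme="C"),
            SampleSpec("A", 6, "ANC_A"),
            SampleSpec("B", 15, "ANC_B"),
            SampleSpec("C", 15, "ANC_C"),
        ),
        mito_mu=2.2e-6,
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=100.0,
        meta={"intended_gp": "GP5", "target_isolate": "FARM", "expected_k1": 3},
    ))

    # GP6: long-isolated sibling lineage, very small deme, near-monomorphic
    # nuclear locus, single first-level cluster.
    scenarios.append(SimScenario(
        name="isolated_sibling",
        inheritance="haplodiploid",
        demes=(Deme("anc", 150, 150), Deme("L", 6, 6), Deme("A", 150, 150),
               Deme("B", 150, 150)),
        events=_radiation(["L", "A", "B"], 8000.0),
        sampling=(
            SampleSpec("L", 6, "SIB", bird_type="pigeon"),
            SampleSpec("A", 10, "ANC_A"),
            SampleSpec("B", 10, "ANC_B"),
        ),
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=100.0,
        meta={"intended_gp": "GP6", "target_isolate": "SIB", "expected_k1": 1},
    ))

    # Motley farm: two unadmixed mito clusters co-occurring in one isolate
    # (very recent secondary contact at similar frequencies).
    scenarios.append(SimScenario(
        name="motley_farm",
        inheritance="haplodiploid",
        demes=(Deme("anc", 150, 150), Deme("A", 150, 150), Deme("B", 150, 150),
               Deme("FA", 300, 300), Deme("FB", 300, 300)),
        events=(
            AdmixturePulse(130.0, "FA", ("A",), (1.0,)),
            AdmixturePulse(132.0, "FB", ("B",), (1.0,)),
        ) + _radiation(["A", "B"], 6000.0),
        sampling=(
            SampleSpec("FA", 10, "MOTLEY", bird_type="layer"),
            SampleSpec("FB", 10, "MOTLEY", bird_type="layer"),
            SampleSpec("A", 10, "ANC_A"),
            SampleSpec("B", 10, "ANC_B"),
        ),
        indel_series=_INDEL_SERIES_8, indel_rate=2e-6,
        ancestry_time=200.0,
        meta={"intended_gp": None, "target_isolate": "MOTLEY",
              "signature": "pi-ratio secondary-contact flag"},
    ))
    return scenarios


def ne_ratio_replicates(
    inheritance: str = "haplodiploid",
    n_replicates: int = 200,
    seed: int = 0,
    N_f: int = 500,
    N_m: int = 500,
    n: int = 20,
    mu: float = 1e-5,
) -> tuple[float, float, int]:
    """Replicated single-deme experiment behind the headline targets.

    Simulates ``n_replicates`` neutral samples with equal per-site mutation
    rates at both loci, computes per-site nucleotide diversity at each locus
    per replicate, and returns (ratio of mean nuclear pi to mean mito pi,
    delta-method standard error of that ratio, n_replicates).  The
    expectation is the nuclear/mito effective copy-number ratio: 3 for a
    haplodiploid deme with N_f = N_m, 4 for a diplodiploid one.
    """
    from .diversity import nucleotide_diversity

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates) % (2**31 - 1)
    pis = np.empty((n_replicates, 2))
    for r in range(n_replicates):
        sc = single_deme_scenario(
            N_f=N_f, N_m=N_m, inheritance=inheritance, n=n, mu=mu,
            seed=int(rep_seeds[r]),
        )
        mito, nuc, _ = simulate(sc)
        pis[r, 0] = nucleotide_diversity([s for _, _, s in mito.sequences])
        pis[r, 1] = nucleotide_diversity([s for _, _, s in nuc.sequences])
    xbar, ybar = pis[:, 0].mean(), pis[:, 1].mean()
    ratio = ybar / xbar
    R = n_replicates
    vx = pis[:, 0].var(ddof=1) / R
    vy = pis[:, 1].var(ddof=1) / R
    cxy = np.cov(pis[:, 0], pis[:, 1], ddof=1)[0, 1] / R
    se = ratio * np.sqrt(vy / ybar**2 + vx / xbar**2 - 2 * cxy / (xbar * ybar))
    return float(ratio), float(se), R
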