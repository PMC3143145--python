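# Methods

`mitonuc` analyses two aligned per-individual sequence fragments — a haploid,
maternally inherited mitochondrial marker (COI-like, 543 bp by default) and a
diploid nuclear fragment with an indel-bearing intron (tropomyosin-like,
729 aligned columns) — to resolve layered admixture histories in a pest mite
species complex: ancient radiation into incipient species, nearly
interspecific hybridization, founder bottlenecks, and very recent secondary
contact ("motley" isolates that pool unadmixed individuals of divergent
lineages). This note documents the models, the numerical choices, the
synthetic-data generator, and the known limits of what the tests demonstrate.

## Inheritance and effective sizes

For a haplodiploid organism (diploid females, haploid males) a deme with
`N_f` females and `N_m` males carries `2*N_f + N_m` nuclear gene copies and
`N_f` mitochondrial copies; with equal sex numbers the nuclear/mitochondrial
effective-size ratio is 3 (it is 4 in a diplodiploid organism,
`2*(N_f+N_m)` vs `N_f`). This ratio is the ground truth the simulator is
calibrated against (`simulate.ne_ratio_replicates`, also the quantity the
acceptance script reports): under neutrality and equal per-site mutation
rates, the ratio of mean per-site nucleotide diversities converges to the
copy-number ratio. It is also why the mitochondrial marker shows a more
recent picture of population structure than the nuclear one — the leverage
the whole mito-nuclear comparison rests on.

## Diversity statistics (`diversity`)

- `pi` is Nei's (1987, eq. 10.5) unbiased per-site nucleotide diversity.
  With sample haplotype frequencies the `n/(n-1)` correction reduces exactly
  to the mean pairwise difference count over unordered sequence pairs
  divided by the post-gap-handling alignment length; that is what is
  computed (for n = 2 sequences differing at 2 of 10 sites, pi = 0.2).
- `Hd = n/(n-1) * (1 - sum p_i^2)` over haplotype frequencies.
- Tajima's D uses the standard 1989 constants and is reported as undefined
  (`None`, never 0) when no site segregates; downstream profile predicates
  treat an undefined D as failing any sign condition rather than erroring.
- Gap handling has two modes throughout the package:
  `ignore_gap_columns` removes every column containing a gap dataset-wide
  before any comparison (keeping haplotype identity transitive, the
  "gaps unconsidered" convention), while `fifth_state` scores `-` as a fifth
  character state. `N` is never a state. Diversity and mismatch statistics
  default to `ignore_gap_columns`; genotype matrices for clustering default
  to `fifth_state`.
- The flag `pi_mito / pi_nuclear > 0.5` marks candidate recent secondary
  contact: with a 3-fold smaller mitochondrial effective size, mitochondrial
  diversity approaching the nuclear one indicates co-occurring divergent
  maternal lineages rather than equilibrium variation. The ratio is
  undefined (and never flagged) when the nuclear diversity is zero.

## LD screening (`ld`)

Both fragments are short and effectively non-recombining, so associated site
pairs are expected and can bias model-based clustering. For every unordered
pair of polymorphic sites (multi-allelic sites dichotomized major-allele vs
rest) the screen reports `r_LD = |r|` of the 2x2 haplotype-count table and a
two-tailed Fisher exact P on the same table. Sites involved in at least one
pair with `P < alpha` (default 0.05) and `r_LD > 0.5` are excluded — both
members of the pair — giving the "filtered" dataset variant whose clustering
is compared with the full one (`compare_clusterings`: equality of the chosen
K, best label-permutation agreement of majority assignments, individuals
changing cluster). No multiple-testing correction is applied; the number of
tests is reported.

A caveat the tests make explicit: on data simulated without intra-fragment
recombination under the infinite-sites model, mutations sharing a genealogy
branch are *perfectly* correlated, so the screen excludes most sites of any
reasonably polymorphic fragment — the regime in which exclusion is a
minority of sites (and in which full-vs-filtered agreement >= 0.95 is
asserted) is the unlinked-differentiated-sites regime, exercised with
Balding-Nichols frequency fixtures. Real data sit between the two regimes
(homoplasy and recurrent mutation break perfect correlations).

## Mismatch distributions and sudden expansion (`mismatch`)

The observed distribution counts pairwise differences over all unordered
sequence pairs (pairs, not collapsed haplotypes). The sudden-expansion
expectation F_j(tau, theta0, theta1) is the exact two-epoch pair-coalescent
solution (equilibrium geometric law plus an exponentially damped convolution
term); the implementation is verified against direct numerical integration
of the pair-coalescence density. Fitting minimizes
`SSD = sum_j (f_j - F_j)^2` over the observed range with bounded multi-start
Nelder-Mead (seed-dependent starts; theta1 capped at 1e5 as an effectively
infinite post-expansion size — the surface is ridge-like in (theta1, tau)).

Goodness of fit simulates coalescent samples of the same size under the
fitted expansion (time in mutational units, mutations Poisson over branches),
refits each, and reports `P = #(simulated stat >= observed)/(B+1)` for SSD
and for Harpending's raggedness `r = sum (x_{i+1}-x_i)^2` (trailing zero
class included). B defaults to 200 and is recorded in the result. The
parametric bootstrap is calibrated: under the model, p_ssd is uniform
(KS-tested in the acceptance suite).

Shape labels: `1h`/`2h` when one or two haplotypes are present; otherwise
`uni`/`bi` by counting local maxima of the 3-bin moving-average-smoothed
frequencies with prominence >= 5% of total mass (a reproducible stand-in
for by-eye labels; both knobs are arguments).

## Admixture-model clustering and deltaK (`clustering`)

The model is the standard admixture mixture model for multilocus genotypes
(haploid mitochondrial sites enter as single copies, diploid nuclear sites
and encoded indel loci as two unordered copies). Gibbs updates: allele-copy
assignments given (Q, P); `P_kl ~ Dirichlet(1 + counts)`;
`Q_i ~ Dirichlet(alpha + counts)`; `alpha` by random-walk Metropolis under a
uniform prior on (0, 10]. Model support is ln P(D) estimated as
`mean(ll) - var(ll)/2` over retained sweeps. Two engines produce the same
model: a numba-jitted kernel (default) and a numpy reference path; a test
cross-checks them, and a toy two-individual/one-locus posterior is checked
against exhaustive enumeration of the assignment space.

Chains start from a seeded k-means++ assignment of individuals (option
`init="random"` restores naive starts). This matters at desk scale: with
random starts, chains of a few thousand sweeps intermittently converge to
different partitions, inflating the between-replicate sd of ln P(D) that
forms the deltaK denominator. Default chain lengths are burn-in 10^4 /
5x10^4 sweeps with 5 replicates per K; the tests and scripted-scenario
analyses use shorter, k-means-initialized chains (burn-in ~300, ~1100
sweeps, 3-5 replicates), which reproduce the same model choices on the
synthetic data sizes used here.

deltaK(K) = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) over replicate means;
the chosen K is the argmax, with ties within 5% of the peak resolved to the
smallest K (noted). The choice is flagged unreliable when no dominant peak
exists (top peak < 4x the second) or when fewer than 20% of individuals are
confidently assigned (max ancestry >= 0.7) — a sharp peak with diffuse Q
rows is not evidence of structure. Two caveats, both visible in the tests:

- deltaK is biased toward K = 2 when true clusters are size-imbalanced;
  scripted scenarios carry anchor isolates sized to balance clusters, as the
  original multi-isolate sampling effectively did.
- a single non-recombining fragment from a *panmictic* population genuinely
  mimics two-lineage structure through its deepest coalescent split (half
  the diploid individuals are "homozygous" for a basal clade). The valid
  null for the unreliability flag is therefore the model's own null —
  unlinked Hardy-Weinberg sites — and distinguishing a panmictic deep
  gene-tree split from a true two-lineage swarm at one locus requires the
  second locus or external context.

The hierarchical protocol re-runs the model choice inside subsets defined
either by an assignment threshold (defaults 0.8 mitochondrial, 0.6 nuclear,
0.7 combined) or by grouping whole isolates whose mean majority ancestry is
>= 0.9 ("homogeneous isolates"); unassigned individuals are recorded.
Inter-cluster heterozygotes are individuals whose two largest ancestry
components both fall in [0.405, 0.595] — the flagging band for F1-like
hybrids between divergent lineages.

## F-statistics (`fstats`)

AMOVA follows Excoffier's decomposition on the matrix of pairwise difference
counts (entering as squared Euclidean distances, the haplotype-distance
convention), with general unbalanced-design coefficients for fully nested
levels: groups / isolates within groups / individuals within isolates /
within individuals. Negative variance components are reported, not
truncated. Phi-statistics follow the usual ratios; Phi_IS is the inbreeding
coefficient F_IS. Permutation schemes per stratum: individuals among
isolates (Phi_ST; the *genotype* is the randomization unit — both alleles of
an individual move together, appropriate when Hardy-Weinberg cannot be
assumed; an allele-unit scheme is available for comparison), isolates among
groups (Phi_CT), individuals among isolates within groups (Phi_SC), alleles
among individuals within isolates (F_IS). P-values use the add-one
convention `(1 + #{perm >= obs})/(n_perm + 1)`; the default n_perm is
10,000 (tests use 99-999).

## Synthetic-data generator (`simulate`)

A discrete-event structured coalescent: exponential waiting times within
demes at rate `k(k-1)/2 / copies`, with pastward-ordered events — splits,
size changes (bottlenecks are sugar for two size changes), and admixture
pulses that reassign lineages to source demes. Mitochondrial lineages can be
routed separately from nuclear ones at a pulse (`mito_proportions`),
modelling maternally biased founding; the sampling plan can place an
individual's second nuclear allele in a different deme (`father_deme`),
constructing exact F1 crosses whose mitochondria follow the maternal deme.
Substitutions are infinite-sites with collision re-draw on the finite
alignment (valid while mutation counts stay well below the length);
intron indel series follow a two-state toggle process on designated
intervals, emitted as gap runs. Identical scenario + seed gives
byte-identical FASTA output. The engine's mean diversity is cross-checked
against msprime on a single-deme configuration, and E[pi] = 2 * copies * mu
is verified for both loci.

What the generator does *not* emulate: intra-fragment recombination,
selection, continuous migration (only pulses), sequencing error, alignment
ambiguity, and homoplasy (each variable site has exactly two states). The
last point matters for the LD screen (above) and means real-data site
counts will exceed simulated ones at equal diversity.

## Scripted scenarios and the genetic-profile classifier (`profiles`)

`classify_gp` is a pure rule cascade over (pi ratio, pi_COI, pi_Tpm, K_T1,
Tajima-D signs), evaluated GP6 -> GP4 -> GP5 -> GP1 -> GP2 -> GP3 with every
comparison recorded in a trace; multiple or zero matches produce an explicit
ambiguity. GP6 is keyed on a single first-level nuclear cluster and GP4 on
ratio > 1.0 (their printed point diversities are exemplars from single
isolates, not thresholds); GP2/GP3's overlapping nuclear-diversity ranges
are discriminated by the cluster count (3 vs 2) and GP3's D-sign condition.
"Diverse D values" is not a computable predicate and is recorded as an
advisory trace entry (no consistent sign across loci). K_T1 counts the
first-level nuclear clusters in which at least one member of the isolate has
ancestry >= 0.4 (capturing homozygous members and heterozygote components);
S_maj is the number of segregating sites in the isolate's majority (> 60% of
sequences) group of mitochondrial haplotypes within two mutational steps of
the most frequent one.

The scripted scenarios give each profile a generative story; parameters were
set from coalescent expectations so that the target isolate's statistics
center inside the profile's windows, and are frozen in
`simulate.scripted_scenarios`:

- **GP1** wild condition: two lineages (split 26,000 generations) fused 30
  generations ago into a large hybrid swarm whose founding mothers all came
  from one lineage — nuclear diversity high, mitochondrial low.
- **GP2** farm with three first-level clusters: a single-propagule founding
  5,400 generations ago (star-like nuclear genealogy), a recent
  few-foundress episode (shallow mitochondrial star), and two recent
  paternal immigrants each from two deeply divergent lineages. The star
  spreads pi over ~100 independent branches and the immigrants put the
  between-lineage component on ~55 deep mutations, keeping pi_Tpm's
  coefficient of variation near 13% — the narrow printed window demands it.
- **GP3** founder bottleneck (2 foundresses, ~10 generations) followed by
  expansion, plus five paternal immigrants from a second lineage: both
  Tajima's D negative, two clusters.
- **GP4** very recent secondary contact at low minority frequency (2 of 20
  individuals from a mito-divergent farm): pi_COI/pi_Tpm ratio well above 1.
- **GP5** recent secondary contact in a three-lineage background
  (heterozygous paternal immigrants at intermediate frequency plus two
  immigrant females carrying a second maternal lineage).
- **GP6** long-isolated sibling lineage: tiny deme, near-monomorphic
  nuclear locus, single first-level cluster.
- plus a **motley farm** scenario (two unadmixed mitochondrial clusters
  pooled 50/50) exercising the pi-ratio secondary-contact flag.

Scenario recovery through the full pipeline is 92-100% over 25 seeded
replicates for GP1-GP4 and GP6. **GP5 sits near 50% and its acceptance test
is expected to fail**: the profile's nuclear-diversity window
(0.0075-0.0120) spans about +/-23% around its center, i.e. ~5.5-8.7 pairwise
differences on a 729-bp fragment, while the D_Tpm > 0 condition forces that
diversity onto a few deep balanced branches, whose mutation-count
coefficient of variation is >= 22% regardless of parameterization; joint
with the ratio window (0.5-1.0) and the pi_COI window, the conjunction
cannot be satisfied in >= 80% of replicates at this locus length and sample
size. (GP2 escapes the same bound only because its row carries no D-sign
condition, so its diversity can ride on many low-frequency deep mutations.)

What passing scenario tests do and do not show: they demonstrate that the
pipeline's statistics jointly discriminate the intended demographic
signatures on clean two-locus data at study-like sample sizes; they do not
demonstrate robustness to homoplasy, sequencing error, unmodelled migration,
or misalignment, and the profile windows themselves remain descriptive
transcriptions of observed isolates rather than estimated decision
boundaries.

## Problem sizes used by the test and acceptance runs

Chosen as the package's own desk-scale defaults: 20-52 individuals per
simulated dataset, 25 replicates per scripted scenario, 200 replicates for
the effective-size-ratio experiment, permutation counts 99-999 in tests
(10,000 as the analysis default), mismatch bootstrap 40-200, and MCMC chains
of ~1,100 sweeps with 3-5 replicates per K (10^4/5x10^4 with 5 replicates as
the analysis default). All sizes are arguments.
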