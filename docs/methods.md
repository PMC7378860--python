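# Methods

## Scope and data model

`coevoseq` analyses serial-transfer deep sequencing of an RNA
replicator ecosystem: a self-replicating host RNA (~2040 nt, encoding the
Qβ replicase β-subunit) and parasitic RNAs that are host molecules with one
large internal deletion, classed by size (parasite-α ~220 nt, β ~1070 nt,
γ ~510 nt). Everything is expressed in 1-based coordinates on the *original
host* reference. A parasite class is defined by a fixed deletion window
`[start, end]`; positions inside a class's window are *masked* for that
class — they carry no information — and positions at or after `start` on a
parasite read are lifted by the window length to host coordinates.

Windows of different classes may overlap or nest. With one window per class
and the canonical product sizes (220/1070/510 from a 2040 nt host), disjoint
windows are arithmetically impossible (the deleted spans sum to more than
the host), and in the biological system the classes do lose overlapping
parts of the replicase gene. Class identity is therefore anchored not in
disjointness but in (a) the recorded deletion event in simulations and
(b) distinct product lengths, which the validator enforces: two classes
whose products collide in one length bin are rejected, as are duplicate
windows. Both termini must survive every window, since the terminal
replicase-recognition regions are retained by all species.

## Synthetic serial-transfer generator

The generator emulates the droplet replication–dilution protocol round by
round:

1. **Compartmentalisation.** Molecule copies are assigned uniformly at
   random to a fixed number of droplets (`initial_population /
   droplet_lambda`, held constant across rounds because the reaction volume
   is fixed), giving Poisson occupancy with a mean that rises and falls
   with the population.
2. **Replication.** In each droplet containing at least one host, every
   molecule replicates: hosts with per-round factor `replication_factor_host`
   (default 8), parasites with factor
   `r_host · (L_host / L_parasite) ^ length_advantage_exponent`
   (default exponent 1) — shorter molecules replicate faster. Droplets with
   no host are inert: parasites cannot supply replicase. Offspring counts
   are Poisson; total output per droplet is capped at `droplet_cap`
   (default 100), the finite-resource limit, with excess resolved
   multinomially. The fixed droplet count times the cap is the carrying
   capacity, validated against `population_cap` up front.
3. **Mutation.** Each offspring copy independently acquires substitutions
   and indels at per-base rates (`substitution_rate` default 1e-5 per base
   per replication, the error rate of Qβ replicase; `indel_rate` default
   1e-6, set an order of magnitude lower as point indels are rarer than
   substitutions in this polymerase). Mutations are stored as events on the
   host reference, so molecules are (reference, mutation-set) pairs and the
   planted truth is exact by construction; sites already mutated in a
   lineage are skipped rather than stacked (collisions are negligible at
   these rates and keep event semantics unambiguous).
4. **Deletion events.** Each new host copy becomes a parasite of a
   randomly chosen configured class with probability `deletion_event_rate`
   (default 1e-3 per replication; the real per-replication rate is far
   lower, but desk-scale populations of 1e3–1e5 molecules need an elevated
   rate for parasites to appear at all, just as 1e9-molecule populations
   make them inevitable within two rounds). Mutations inside the class
   window are dropped from the child; the event (round, parent, child,
   class) is recorded.
5. **Dilution.** Every copy survives independently with probability
   `dilution_keep` = 0.2 — removal of 80% of the droplets, i.e. five-fold
   dilution. Mixing between rounds is modelled as full pooling (fresh
   droplet assignment each round), reflecting the vigorous fusion–division
   mixing step.

Populations are snapshotted after replication (when sequencing samples
would be drawn); the truth records per-round, per-class mutation
frequencies, all deletion events, and the molecule parentage map, in which
every parasite's ancestry crosses exactly one deletion event.

**Read sampling** draws `n` reads multinomially by copy count and flips
each base independently with `seq_error_rate` (default 1e-3, a post-CCS
residual error level); optional CCS pass counts are 1 + Poisson. A separate
`planted_population` constructor builds populations with exact haplotype
frequencies for recovery experiments.

What the generator deliberately does **not** model: replicase/translation
biochemistry and fitness effects of individual mutations (all mutations are
neutral apart from the length advantage), oil-phase physics, template
secondary structure, recombination, and coverage truncation (reads are
full-length). Passing recovery tests on this generator therefore
demonstrates that the *analysis* stages are correct and calibrated, not
that they would be robust to, e.g., systematic PacBio indel error or
partial reads in real data.

## Mutation calling

Reads are aligned globally (Needleman–Wunsch, affine gaps) to their class
reference via Biopython's `PairwiseAligner`, configured as match +1,
mismatch −2, gap of length *k* scoring −4 − (*k* − 1); the first optimal
alignment of the engine's deterministic enumeration is used, which fixes
tie-breaking. `N` scores 0 against every base and yields an *ambiguous
site*, never a substitution event. Mismatch columns become substitutions;
each deleted reference base becomes its own deletion event (so multi-base
deletions decompose, keeping substitution/insertion/deletion bookkeeping
well defined); each reference-gap run becomes one insertion anchored after
the preceding reference position (a leading insertion is anchored at
position 1). Alignments are cached per distinct sequence, which collapses
the cost of deep read pools dominated by a few genotypes. Sequences beyond
20 kb must be supplied pre-aligned; a pre-computed alignment that includes
the original host as a row is consumed directly (`aligned-fasta`),
bypassing the internal aligner, with a parasite row's long deletion gap
suppressed from its event set.

The frequency table holds `(round, class, event, count, depth, frequency)`
with depth = retained reads of that class in that round (full-length
coverage is assumed). Empty (round, class) groups are absent, not
zero-frequency rows — a consequence is that persistence tracking can only
see rounds in which the class yielded at least one called event.

**Dominance** is strict: frequency > threshold (default 0.10) in at least
one (round, class). The threshold is applied per round and per class, not
to pooled rounds. Several dominant events may share a reference site; the
caller reports both the event count and the distinct-site count.

**Genotype projection** maps each read to its 0/1 vector over the dominant
events, masked inside its class's window. Reads with an ambiguous base at
an unmasked dominant site are dropped (vectors must be total). Identical
vectors pool within (round, class); frequencies are normalised over the
whole group *before* truncation to the top `top_n` (default 90) — top-n is
a selection step, not a re-normalisation — and rank ties break
lexicographically for determinism.

## Genotype space

The masked Hamming distance counts sites unmasked in both genotypes that
differ; the large deletion contributes zero, so a parasite that matches a
host at every retained site is at distance 0. The map is built from the
matrix *D* of **squared** distances: *K* = −½·*C·D·C* with
*C* = *I* − **11**ᵀ/*n*, symmetric eigendecomposition, eigenvalues sorted
descending, and coordinates (√λ₁·e₁ᵢ, −√λ₂·e₂ᵢ). With this scaling the
embedded separation of two genotypes at Hamming distance *h* is exactly
*h*, and any *D* built from squared Euclidean distances of a planted
configuration is reproduced to numerical precision. A
`literal_eigenvalue_scaling` flag scales by λ instead of √λ for
comparability with the eigenvalue-scaled variant of the coordinate
formula; it rescales axes (anisotropically) and is off by default.
Numerical conventions: the kernel is re-symmetrised against round-off;
eigenvector signs are fixed by making the first non-zero component
positive; a non-positive λ₂ zeroes the second axis and sets a degeneracy
flag; the negative-eigenvalue mass |Σλ₋|/Σ|λ| is reported because a
squared-Hamming matrix need not be Euclidean (with binary unmasked vectors
it is — Hamming equals squared Euclidean there — but masking can break
it). All rounds and classes are embedded jointly in one map; per-round
views are filters of the joint coordinates.

Edges: within-class pairs at unsquared distance 1, cross-class pairs at
masked distance 0 (candidate parasite-generation events). The edge set
exports to `networkx` for network analysis.

## Lineage analysis

"Unique" parasite mutations are dominant mutations of a parasite class, at
sites inside the class's retained region, whose host frequency never
exceeds the dominance threshold in any sequenced round. Threshold mode
(default) rather than literal absence is used because sequencing error
makes a literal zero unattainable in real data; an `absent` mode (zero
host reads) is provided for comparison. Persistence tracks list the rounds
a mutation stayed above threshold, with gap rounds between first and last
appearance. Origin matching searches the same round and all earlier
sequenced rounds for host genotypes at masked distance 0 from each
parasite genotype (generation may predate sampling), nearest round first;
every same-round origin pair is by construction also a cross-class edge.

## Design choices that were genuinely open

- **Growth model**: no kinetics are prescribed by the protocol; per-droplet
  geometric growth with a single length-advantage exponent is the simplest
  model that makes shorter parasites out-replicate hosts.
- **Fixed droplet count**: the droplet count is pinned to the initial
  population over `droplet_lambda` rather than scaling with the population,
  because the reaction volume is fixed; this provides the carrying capacity
  that keeps simulations bounded.
- **Per-read pairwise alignment** replaces a multiple-sequence alignment of
  each sample: coordinates stay deterministic, no external tool is needed,
  and the pre-aligned input path exists for exact reproduction of analyses
  built on an existing MSA.
- **Overlapping class windows allowed** (see data model above); the
  alternative — rejecting overlap — cannot represent the canonical class
  structure.
- **√λ axis scaling** as the default reading of the coordinate
  construction, because it is the standard principal-coordinate scaling
  under which map distances estimate the input dissimilarities; the literal
  λ-scaled variant is one flag away.

## Problem sizes and tolerances

The test suite and the acceptance script run on scaled-down instances
chosen to exercise every code path at desk scale: 120–400 nt hosts with
proportionally scaled windows and 3–6 rounds for simulation-driven checks,
and the full 2040 nt host with canonical windows for planted-mixture
recovery at depth 2000 (error-free reads there keep the alignment cache
small, since recovery of planted frequencies, not error robustness, is
what those checks measure). Exact assertions (aligner score vs oracle,
dominant-set equality, edge/origin recovery) use no tolerance; stochastic
recovery uses 3 standard errors of the relevant binomial/multinomial;
linear-algebra identities use 1e-9.

## Known limitations

- Neutral mutations mean the simulator cannot reproduce selective sweeps,
  arms-race turnover, or concentration trajectories; it validates recovery
  machinery, not evolutionary dynamics.
- Reads are full-length; partially covering reads would require per-site
  depth bookkeeping that the frequency table's schema anticipates (depth
  column) but the caller does not yet implement.
- The aligner's engine-determined tie-breaking among co-optimal gap
  placements is deterministic but not guaranteed leftmost; calls at
  homopolymer boundaries may differ from an aligner with a different
  convention while scoring identically.
- `PersistenceTrack` gaps are only observable in rounds where the class
  produced at least one called event (see frequency-table semantics).
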