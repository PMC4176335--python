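# Methods

## Scope and model

`rmscape` analyses ordered, strand-aware gene models over one or more
replicons (chromosome / plasmid / phage, labels taken from input metadata
and never inferred). All neighbourhood logic runs on *gene ranks* — the
0-based position of a gene in the coordinate-sorted order of its replicon.
"N genes apart" always means a rank offset of N (adjacent genes are one
apart), and printed thresholds map directly onto comparison operators:
"less than four genes apart" is `offset < 4`. Strand never enters distance
or neighbourhood computations. Circular replicons wrap (distances take the
shorter arc, windows wrap across the origin); linear replicons truncate.
The alternative reading of "N genes apart" as the number of *intervening*
genes is one off from rank offset; rank offset was adopted because it maps
printed numbers onto operators without reinterpretation.

Partial CDS, CDS lacking a terminal stop codon and CDS with an internal
stop are rejected at load time and accounted for in a load report, so
dropped genes are always conserved in the bookkeeping.

## Detection rules and their parameters

| parameter | default | meaning |
|---|---|---|
| `max_gap` | 4 | components of one system are < 4 ranks apart |
| `solitary_gap` | 10 | solitary iff nearest cognate ≥ 10 ranks away |
| role e-value surrogate | < 1e-3 | hit retention for role calls |
| subject coverage | ≥ 0.5 | extra filter for Type II / IV REase roles |
| BBH similarity / length | ≥ 0.8 / ≤ 0.2 | ortholog-candidate filters |
| synteny support | ≥ 4 in ±5 genes | positional-orthology refinement |
| pan identity | 0.8 / 0.4 | stringent / relaxed families |
| pan coverage | > 0.8 of smallest | single-linkage edge condition |
| spacer identity / length | ≥ 0.9 / < 0.1 | protospacer match retention |
| competence run | gap ≤ 5, ≥ 6 genes | locus definition; PilU/ComC facultative |
| dS saturation | > 1 | estimate discarded from summaries |

The band [`max_gap`, `solitary_gap`) is undefined by the two printed
thresholds; genes whose nearest cognate falls there are reported as
`ambiguous` rather than silently classified. Unassigned S subunits land in
the same bucket, so every REase/MTase/S gene is in exactly one of
{system member, solitary, ambiguous}.

An REase passing both Type II and Type IV references is resolved by genomic
context: a compatible MTase within `max_gap` makes it Type II, otherwise
Type IV. A single gene passing both an REase and an MTase reference of any
type label is called IIC ("a gene encoding both functions"); this covers
both genuine IIC-lineage proteins and head-to-tail fusions of two-gene
systems, which is exactly what the fusion scan afterwards quantifies
(similarity > 0.5 to a two-gene Type II system with > 0.5 query coverage).

Cross-type proximity clusters are chained per type, so a Type I system with
a Type II MTase nearby yields one Type I system plus an independent
classification of the MTase; merging ("curation of multiple occurrences")
applies within a type only. Trans-acting systems with components in distant
loci are deliberately not inferred.

## Alignment machinery

Pairwise protein comparison uses a substitution-matrix dynamic-programming
aligner (BLOSUM62, gap open −11, extend −1) in two modes: Smith–Waterman
local and end-gap-free global. The significance surrogate is a
Karlin–Altschul transform `E = K·m·n·exp(−λS)` with gapped-BLOSUM62
constants (K = 0.041, λ = 0.267); it is only ever compared against a fixed
threshold, so any monotone surrogate would serve. "Similarity" is the
fraction of aligned columns with a positive substitution score — the 80%
BBH filter needed a matrix-level definition and this is it, fixed in one
place. Precomputed BLAST tabular (outfmt 6) hits can be ingested in place
of the built-in aligner; identity then stands in for similarity
(conservative, since positives ≥ identities).

All-against-all and library scans are pre-screened by a shared-4-mer count
(≥ 3 shared 4-mers): unrelated random proteins share ≈ 0.1 4-mers in
expectation while ≥ 60%-identical pairs share dozens, so the screen is
effectively lossless for the similarity regimes the thresholds operate in.
Every scanning function accepts `prefilter=False` for exact behaviour.

MCL clustering adds self-loops at the weight of the heaviest incident edge,
iterates expansion/inflation to a 1e-6 max-change tolerance (≤ 200
iterations, error on non-convergence) and reads families off the attractor
structure. Ties everywhere break lexicographically on identifiers.

## dN/dS estimation

Both estimators share documented counting conventions: mutations to stop
codons are excluded from site opportunity; each codon carries three sites
split proportionally to its weighted synonymous fraction (so S + N = 3L);
gap-bearing codon columns are deleted pairwise; ω is undefined at dS = 0;
dS > 1 flags saturation (dS = 1 exactly is retained); the universal code is
a package constant.

`ng86` weights every legal single-nucleotide change equally, enumerates all
substitution pathways between differing codons (stop-crossing pathways
discarded; if all cross a stop, all orderings are kept), and corrects with
Jukes–Cantor. `yn00` estimates κ from fourfold-degenerate third positions
via the K80 formulae (falling back to 1 below 10 usable sites), weights
site opportunity by κ and F3x4 position-specific nucleotide frequencies,
weights multi-hit pathway orderings by their κ/ω likelihood with ω iterated
to self-consistency (≤ 30 rounds, 1e-4 tolerance), and corrects the
synonymous and nonsynonymous classes separately with K80. With κ fixed at 1
the two estimators agree within a few percent on neutral-parameter
simulations; under κ = 2 simulation, `yn00` recovers planted ω essentially
unbiased while `ng86` shows its classic ≈ 15% downward bias.

## What the generator emulates — and what it does not

The synthetic-data module is the package's study system. It emulates:
labelled reference proteins with divergent copies at controlled identity
tiers (0.95/0.70/0.40); genomes assembled from feature blocks separated by
≥ 11 background genes, planting systems of every type at controlled
component offsets, solitary genes, ambiguous-band decoys, MGE spans,
integron and competence loci, MOB+/MOB−/conjugative plasmids and CRISPR
spacers copied from planted genes with interior mutations (≥ 3 positions
from the ends, so ungapped local alignment never trims them) or with
deliberately unalignable tails that exercise the length-difference rule;
and clades derived from a 320-gene ancestor by per-strain insertions,
deletions and one 8-gene inversion, with every retained gene diverged under
the codon process below.

Planted R-M genes are founder coding sequences diverged under the codon
process (t = 0.25, κ = 2, ω = 0.15), giving ≈ 90% protein identity to the
founder — far above every role-call threshold — and sub-saturation dS
between siblings. Solitary genes descend from founders distinct from the
system lineages, so solitary and complete-system proteins never share a
pan-genome family by construction (the property the family-overlap analysis
measures). Background genes are random-codon sequences rejection-sampled to
share no k-mer signal with the library, making spurious role calls
structurally impossible. The generator re-validates every planted
constraint after assembly and raises on violation.

Event slots in clades are allocated disjointly with a 7-gene buffer —
wider than the 5-gene synteny half-window — so one event never erodes the
neighbourhood support of genes flanking another; the buffer is a config
field and gene-order-only studies (`sequences=False`) may narrow it. The
breakpoint decoy plants an element against another strain's inversion edge
so that breakpoint flagging is exercised with known truth.

The codon process is a continuous-time Markov jump process (synonymous
rate ∝ 1, nonsynonymous ∝ ω, transitions ∝ κ, stops forbidden) with rates
normalised so the expected substitution count per codon, averaged over the
input sequence, equals t; per-codon event counts are Poisson with the
codon's own relative rate, so low-opportunity codons (Met/Trp) evolve
slowly rather than being forced into ω-independent nonsynonymous changes.
Event counts are drawn from the initial codon's exit rate (not re-drawn as
the codon wanders), a first-order approximation that is irrelevant at the
divergences used.

What passing tests therefore show: the *rules* are implemented exactly and
the estimators are calibrated under the stated model. What they do not
show: robustness to annotation noise, pseudogenes, draft assemblies,
compositional bias, codon-usage bias, non-star phylogenies, paralog-rich
families, or reference libraries with real-world cross-role homology —
planted features are constructed to respect the thresholds they exercise,
so real-data recall will be lower than the synthetic 100%.

All randomness flows through a counter-based generator (numpy Philox);
one seed reproduces every dataset and every result table byte for byte.

## Statistical tests

Spearman's ρ uses average ranks for ties, full-enumeration exact p for
n ≤ 8 (8! permutations, vectorised; exhaustive enumeration beyond that is
astronomically infeasible) and the t-approximation above. Mann–Whitney U
uses the exact interleaving-count null (cached per sample-size pair) when
C(n₁+n₂, n₁) ≤ 20 000 without ties, full label-assignment enumeration with
ties, and the tie-corrected normal approximation otherwise. The binomial
test is an exact tail sum at any n. Chi-square is Pearson's statistic with
the asymptotic upper tail; against full enumeration of fixed-margin 2×2
tables at n = 40 it agrees to ≈ 0.02 in the rejection tail, while near the
null the conditional distribution's discreteness (probability steps of
~0.2) makes any continuous approximation diverge — calibration there is
checked as a rejection-rate property instead. Type-I calibration of the
discrete binomial test is assessed at n = 250, where its achievable size
(0.0497) essentially equals the nominal 0.05; at n = 100 the achievable
size is 0.035, below the calibration band through no fault of the
implementation.

Defaults are two-sided; the per-species region-size comparison is one-sided
(the claim is directional: complete systems in smaller regions). Raw
p-values are reported; a Benjamini–Hochberg column can be attached for
transparency but never gates a result.

## Problem sizes

The shipped study conditions are sized for a single CPU: 20 genomes of
~80–110 genes (2 clades), a 320-core-gene clade for alignment-based core
construction, 240-gene-ancestor clades in gene-order-only mode for the
100-run region-direction experiment, 300-codon pairs × 100 seeds per ω for
estimator recovery, and 1000 simulations per test for type-I calibration.
The full suite and the acceptance script each complete in about one to two
minutes.

## Known limitations

* The e-value surrogate is score-monotone, not a calibrated BLAST e-value;
  only its comparison against 10⁻³/10⁻⁴ thresholds is meaningful.
* `yn00` here is a counting method with the published weighting ideas, not
  a reimplementation of any particular program's numerics; ML codon models
  are out of scope.
* Core-genome construction assumes one positional ortholog per strain;
  paralog tree reconciliation and phylogeny-aware cores are out of scope.
* Prophage/ICE/IME spans, CRISPR spacers and cas presence are inputs, not
  predictions; their detection belongs to dedicated tools.
* Association tests are not phylogenetically corrected; clade structure can
  confound co-occurrence signals on real data.
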