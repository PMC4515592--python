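# Methods

This note documents the models implemented in `mtphylo`, the defaults and
why they were chosen, the numerical conventions, and what validation on
synthetic data does and does not establish.

## Coordinate system and haplotype calling

All positions are 1-based rCRS coordinates on closed intervals; the HVS-I
window 16090–16365 therefore spans 276 positions. The package does **not**
align: input FASTA must be positionally aligned to the reference (gaps
allowed), or declared as a fragment with an explicit start coordinate.
De-novo alignment would dominate the codebase and is better served by
dedicated tools.

Variant calling walks the aligned columns: sample gaps become deletions,
reference gaps become insertions anchored to the preceding reference
position with a sub-index (`573.1C` style), and IUPAC ambiguity codes are
no-calls that never produce variants. Insertions and deletions are excluded
from all dating by default, since mutation-count clocks do not model them.

Synonymy is decided by translating the codon containing the position before
and after the change under the vertebrate mitochondrial code (NCBI table 2),
using the packaged protein-coding gene map (real rCRS gene coordinates;
ND6 is read from the light strand). Three conventions needed fixing where
the biology is ambiguous:

- overlapping gene pairs (ATP8/ATP6, ATP6/CO3, ND4L/ND4) are trimmed to
  non-overlapping classification intervals — a position in an overlap is
  classified against the upstream gene only, so synonymy is single-valued;
- terminal incomplete codons (stops completed by polyadenylation) are
  treated as non-coding;
- anything outside the protein-coding map (control region, rRNA, tRNA) is
  `not_coding`, and the synonymous counting rule excludes it.

The rCRS reference sequence itself is an input, not packaged data. The
synthetic module provides a deterministic stand-in reference
(`synthetic_reference`, fixed internal seed) used by all simulations and
tests; it is explicitly *not* the real rCRS, only coordinate-compatible.

The list of positions masked before phylogenetic reconstruction is a config
input with an empty default; no canonical list is hard-coded.

## Reduced-median network and tree extraction

Haplotypes are binary-encoded (0 = reference state, 1 = derived), invariant
columns dropped, duplicate rows collapsed with sample multiplicity, and
characters weighted by inverse relative frequency binned to integers 1–99:
a frequent mutation gets a low weight, encoding the conventional judgement
that frequent (often hypervariable) sites are the ones likely to recur.

Compatibility is tested against the known ancestral (reference) state: two
characters conflict when the derived-state patterns (1,1), (1,0), (0,1) all
occur. Conflict-free data admit a unique perfect phylogeny, built directly
from the laminar containment order of the characters' taxon sets; every
character labels exactly one edge, and chains of single-step latent
intermediates subdivide multi-mutation branches. Latent intermediates are
*not* median vectors — median vectors arise only from conflict resolution.

For conflicting data, the node set is closed under componentwise-majority
medians of node triples, distance-1 nodes are joined, unobserved dead ends
pruned, and remaining components connected by minimal single-step chains.
A conflict between characters whose weight ratio reaches the reduction
threshold (default 2, as in the original reduced-median formulation) is
resolved in the network by deleting one edge of the *rarer* character per
conflict cycle, so the frequent character is the one that recurs; conflicts
between comparable weights keep their cycles.

`extract_tree` reduces the network to one rooted mutation-labelled tree: a
shortest-path spanning tree from the root (typically the all-zero reference
state) with edge cost equal to character weight. This places high-frequency
mutations as deep as possible and, where a cycle forces a character to
recur, duplicates the frequent one. All remaining ties break
lexicographically by (weight, position, derived base, parent state), making
the output fully deterministic. Because every network edge carries exactly
one mutation, every spanning tree has the same parsimony score; the
frequency rule chooses *which* minimum-parsimony resolution is reported.
Positions struck on more than one edge are reported by
`recurrent_positions()`, and dating counts each occurrence.

## Rho dating

For node *a* with *n* sampled lineages below it, rho is the mean number of
counted mutations from *a* to its tips, computed by the edge-sum identity
`rho = Σ_e m_e·n_e / n`; the standard error is the genealogy-aware
estimator `sigma² = Σ_e (n_e/n)²·m_e`. Duplicate haplotypes contribute
their full sample multiplicity to `n` and `n_e`.

Counting rules: `all_substitutions` (indels never count),
`synonymous_only` (only classified-synonymous substitutions; non-coding
counts as excluded), and `fragment` (substitutions within a window).

Clocks are pluggable `(name, years_per_substitution, counting_rule)`
records. The two shipped whole-genome clocks are the published
purifying-selection-corrected linear rates — one substitution per 3,624
years (whole molecule) and one synonymous substitution per 7,884 years —
applied as-is; the underlying time-dependent correction curve is not
reproduced, but a user can supply any rate. Fragment clocks rescale a base
rate by (base segment length / fragment length); both base values are
required configuration, since published HVS-I rates vary by window. The
package's simulations use 1 substitution per 20,180 years for the 276-bp
window 16090–16365, the classic pedigree-independent HVS-I transition-rate
calibration for exactly that fragment.

Ages are rho × rate with a 95% normal-approximation interval
age ± 1.96·sigma·rate, the lower bound clamped at zero — matching the
convention of published clade-age tables. The normal approximation is the
method's known weak point at small mutation counts; measured coverage on
simulated 20-tip clades with ~25 mutations per lineage is ≈94.5%.

## Founder analysis

`founder_age` computes rho and sigma exactly as above but with tip weights
restricted to sink-region samples, dating the arrival of a lineage in the
sink. When every tip below the node is a sink tip this reduces exactly to
plain clade dating (asserted on random trees).

Founder nodes are user-designated; `scan_founder_candidates` is an
explicitly heuristic helper: it returns nodes subtending at least
`min_sink_tips` (default 3) sink lineages whose own haplotype state is
contained in some source-region tip's variant set — i.e. the founder type
is carried by, or ancestral to, sampled source lineages. This mirrors the
practice of reading founder nodes off a network by eye, and like that
practice it can miss founders whose type was not sampled in the source.

## Population comparison

FST is the AMOVA fixation index: variance components from sums of squared
molecular distances, with haplotype identity (0/1) as the default distance
(conventional frequency-based FST) and pairwise position differences as the
PhiST-like alternative. Unbiased variance components can be negative;
estimates are reported as computed but floored at zero before Slatkin
linearization FST/(1−FST) and ordination. Note the estimator is *not*
exactly zero when a sample is compared with its own copy — it is negative,
as Arlequin also reports.

Significance is by permutation of individuals between the two samples
(default 10,000 permutations, seeded), `p = (1 + #{FST* ≥ FST}) /
(perms + 1)`; p-values are Bonferroni-corrected. The merging rule pools,
within user-declared candidate groups (same ethnic group across studies, or
same country), populations connected by non-significant corrected FST.
Population-size inclusion (default > 30 individuals) applies in the
pipeline stage.

MDS minimizes Young's S-stress, `sqrt(Σ(d² − δ²)² / Σδ⁴)`, from a
classical-scaling (eigendecomposition) start, refined by quasi-Newton
(L-BFGS-B) descent with an analytic gradient — chosen over a hand-written
majorization loop because the objective and start are identical and the
library optimizer is better tested; the procedure is deterministic (no
random restarts). The reported S-stress is the terminal normalized value.
No numeric equality with any particular SPSS ALSCAL/PROXSCAL output is
claimed.

Haplogroup composition classifies lineages by motif containment against a
user-supplied classifier (label → required HVS-I variants); the most
specific match wins, a match whose defined subclades all fail falls back to
the starred paragroup (e.g. `L2*`, since some subclades are invisible to
HVS-I), and matching two disjoint top-level labels is an error.

## Synthetic data

The simulator is a matrilineal (haploid) Kingman coalescent: Ne is the
female effective size, k lineages coalesce at rate k(k−1)/2 / (2Ne) per
generation, so E[T₂] = 2Ne generations — the calibration oracle used in
tests. Exponential growth at rate r per generation shrinks the population
backwards as Ne·e^(−rt) via the usual time transform. Branch lengths are
converted to years with a 25-year generation time. Mutations are Poisson
per branch (rate per lineage per year) at positions drawn without
replacement from the unmasked site pool — strict infinite sites within a
replicate — with synonymy classified against the synthetic reference; a
target synonymous fraction can be rejection-sampled.

Scenario defaults are meant as realistic study conditions, not tuning
knobs:

- **panmictic** (whole-mtDNA): n = 20 genomes, Ne = 1000, rate 1/3,624 yr —
  expected TMRCA ≈ 95 ka, emulating a deep African haplogroup;
- **source/sink** (HVS-I): 100 source + 20 sink lineages, source Ne = 2500,
  sink Ne = 1000, one founder at 11 ka (the Pleistocene/Holocene
  transition), rate 1/20,180 yr on 16090–16365. The migrating lineage is a
  source lineage at the founder time: the planted founder node joins the
  sink clade onto a sampled source lineage, so the founder haplotype is
  carried by source ancestry by construction;
- **island pair** (HVS-I): two samples of 30, Ne = 1500; with divergence
  knob d, each individual is with probability d a population-private
  haplotype, otherwise a draw from a shared coalescent-derived haplotype
  pool. d = 0 is the exchangeable null; d = 1 gives FST = 1.

HVS-I scenario Ne values were chosen so expected segregating sites stay
well below the 276 available positions (mean pairwise differences ~5–8,
typical of real HVS-I samples); much larger Ne would exhaust the fragment
and break the infinite-sites assumption.

What the simulator does *not* model: recombination (absent in mtDNA),
selection, heteroplasmy, rate heterogeneity across sites (hypervariable
positions), back mutation, or sequencing error. Passing tests therefore
validate the estimators under their own assumptions; on real data,
homoplasy at hypervariable sites and the time-dependence of the clock are
additional error sources the tests do not probe.

## Validation problem sizes

The test suite's Monte-Carlo batteries use: 2,000 pairwise-TMRCA
replicates (5% tolerance on the closed form), 300 mutation replicates on a
fixed 20-tip genealogy (unbiasedness within 2 SE), 1,000 full-pipeline
replicates for CI coverage (≥93% bar; the larger battery keeps the
binomial error on the estimate well below the margin), 500 null island
pairs at n = 30 with 199 permutations each (rejection ≤ 7.5% at nominal
5%), 500 random trees for the rho/sigma oracle equivalence (1e-12), and
200 colonization replicates for founder-time recovery (3-SE band around
11 ka; planted-node identification ≥ 90% over 100 replicates). Exhaustive
spanning-tree comparisons are limited to ≤ 10 haplotypes.

## Known limitations

- The reduced-median reduction rule is this package's documented
  interpretation (delete one rare-character edge per dominated conflict
  cycle); the closed-source Network tool's outputs are not replicated
  bit-for-bit.
- The rho CI is a normal approximation and mildly undercovers for sparse
  clades; zero-clamping makes the lower bound conservative.
- Founder scanning requires the founder type (or an ancestor of it) to be
  sampled in the source region.
- Median closure is exponential in the worst case; a node budget guards
  against pathological conflict structures, and large conflicted datasets
  should be pre-partitioned into haplogroups.
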