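# mtphylo

Phylogeographic analysis of human mitochondrial DNA haplogroups: a tested,
reusable implementation of the classic mtDNA toolkit — sequence-to-haplotype
conversion against the rCRS, reduced-median networks, rho-statistic clade
dating with genealogy-aware errors, founder analysis of migrations, and
HVS-I population comparison — validated end-to-end on coalescent-simulated
data with known truth.

## Who this is for

Population geneticists and molecular anthropologists who date mtDNA clades
and migrations from haplotype data. The steps are usually spread across
closed or GUI tools (Network, Arlequin, SPSS); `mtphylo` provides them as a
single scriptable, seeded, unit-tested Python library with a thin CLI.

## The methods

**Haplotypes.** Sequences aligned to the 16,569-bp revised Cambridge
Reference Sequence (rCRS) are converted to variant sets (PhyloTree-style
names such as `A16189C`). Substitutions are classified synonymous /
non-synonymous / non-coding with the packaged mitochondrial gene map and the
vertebrate mitochondrial genetic code; indels and masked positions can be
excluded; the 276-bp HVS-I window 16090–16365 can be extracted.

**Networks.** Haplotypes are binary-encoded against the reference state and
assembled into a reduced-median network; character weights are inverse
mutation frequencies. Compatible data yield the unique perfect phylogeny;
conflicts produce median vectors and cycles, resolved (when extracting a
single rooted tree) so that the higher-frequency mutation sits deeper and is
the one allowed to recur.

**Dating.** For a clade ancestor *a* with *n* descendant lineages, the rho
statistic is the mean number of mutations from *a* to each tip,

```
rho = (1/n) Σ_tips m(a→tip),    sigma² = Σ_edges (n_e/n)² m_e
```

with `m_e` counted mutations on edge *e* and `n_e` lineages below it
(the genealogy-aware standard error). Age = rho × clock rate, with a
normal-approximation 95% CI clamped at zero. Shipped clocks: the corrected
whole-mtDNA rate (1 substitution / 3,624 yr), the synonymous rate
(1 / 7,884 yr), and fragment-scaled clocks for control-region windows.

**Founder analysis.** A migration into a sink region is dated by computing
rho from a designated founder node over sink-region tips only;
`scan_founder_candidates` proposes founder nodes whose haplotype state is
carried by (or ancestral to) source-region lineages.

**Population comparison.** Pairwise FST is the AMOVA fixation index on
haplotype-identity (or pairwise-difference) distances, with permutation
p-values, Bonferroni correction, a pooling rule for non-differentiated
samples, Slatkin linearization FST/(1−FST), metric MDS minimizing Young's
S-stress, and haplogroup composition tables with the `L2*` fallback for
lineages HVS-I cannot place in a subclade.

**Simulator.** A matrilineal Kingman coalescent (pair coalescence rate
1/(2·Ne) per generation, optional exponential growth) with infinite-sites
Poisson mutations over rCRS coordinates, plus source/sink colonization and
island-pair scenarios with the planted truth (TMRCA, founder node and time)
recorded.

## Worked example

```python
import mtphylo as m

cfg = m.SimConfig(seed=1, n_samples=20)          # Ne = 1000 females, 25-yr generations
res = m.simulate_panmictic(cfg)
print(f"true TMRCA: {res.true_tmrca_years:.0f} years")

mat = m.BinaryMatrix.from_haplotypes(res.haplotypes)
zero = (0,) * mat.rows.shape[1]
net = m.build_reduced_median(mat, root_state=zero)
print(f"network: {len(net.nodes)} nodes, {len(net.edges)} edges, "
      f"{net.n_median_vectors} median vectors")

tree = m.extract_tree(net, zero)
est = m.date_node(tree, tree.node_id, m.WHOLE_MTDNA_CLOCK)
print(f"rho = {est.rho:.2f} over n = {est.n_tips} lineages")
print(f"age = {est.age_years:.0f} years, 95% CI [{est.ci95[0]:.0f}, {est.ci95[1]:.0f}]")
```

prints

```
true TMRCA: 104109 years
network: 109 nodes, 108 edges, 0 median vectors
rho = 25.00 over n = 20 lineages
age = 90600 years, 95% CI [65547, 115653]
```

The simulated clade coalesces 104 ka ago; its 108 infinite-sites mutations
assemble into a conflict-free network (the unique perfect phylogeny), and
the rho estimate of 25 mutations per lineage × 3,624 yr dates the root to
90.6 ka with a 95% interval that covers the truth.

The same stages run from the shell: `mtphylo simulate`, `mtphylo haplotype`,
`mtphylo network`, `mtphylo fst`, `mtphylo mds`, or `mtphylo run-all
config.yaml` for a manifest-tracked pipeline run.

## Layout

- `src/mtphylo/sequence_io.py` — rCRS variant calling, synonymy, masking, fragments
- `src/mtphylo/network.py` — binary encoding, reduced-median network, tree extraction, clade labels
- `src/mtphylo/dating.py` — rho, Saillard sigma, clocks, clade age tables
- `src/mtphylo/founder.py` — founder ages over sink tips, candidate scanning
- `src/mtphylo/popgen.py` — AMOVA FST, permutation tests, merging, MDS, composition
- `src/mtphylo/synthetic.py` — coalescent simulator and scenario generators
- `src/mtphylo/cli.py` — pipeline orchestration and click commands
- `docs/methods.md` — model assumptions, parameter choices, limitations
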