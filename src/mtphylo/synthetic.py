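"""Synthetic data with known truth: coalescent genealogies, mutations, scenarios.

Everything the pipeline consumes can be generated here with the true answer
recorded: clock-like matrilineal (haploid) Kingman genealogies with branch
lengths in years, infinite-sites Poisson mutations over rCRS coordinates,
source/sink colonization scenarios with a planted founder node and time, and
paired island populations with a controllable divergence knob for FST tests.

Conventions: the coalescence rate for k lineages is k(k-1)/2 / (2*Ne) per
generation, so a pair of lineages has expected TMRCA 2*Ne generations
(Ne = female effective size; mtDNA is maternally inherited).  Exponential
growth at rate r per generation shrinks the population backwards in time as
Ne * exp(-r t).  Defaults emulate a deep African mtDNA clade: 20 sampled
genomes, Ne = 1000 females, 25-year generations (expected TMRCA ~95 ka),
mutations at the corrected whole-mtDNA rate of one substitution per
3,624 years over 16,569 sites.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace as dc_replace
from functools import lru_cache
from typing import Iterable

import numpy as np

from .network import PhyloNode, to_newick
from .popgen import PopulationSample
from .sequence_io import (
    HVS1_END,
    HVS1_START,
    RCRS_LENGTH,
    Annotation,
    Haplotype,
    Variant,
    apply_variants,
    classify_synonymous,
    default_annotation,
)

#: package default HVS-I clock for nps 16090-16365: 1 substitution / 20,180 yr
HVS1_YEARS_PER_SUB = 20180.0

_BASES = "ACGT"
_REFERENCE_SEED = 160569  # fixed: all simulations share one stand-in reference


@lru_cache(maxsize=4)
def synthetic_reference(length: int = RCRS_LENGTH, seed: int = _REFERENCE_SEED) -> str:
    """Deterministic synthetic stand-in for the rCRS reference sequence.

    A uniform-random nucleotide sequence of rCRS length; it is *not* the real
    rCRS, only a coordinate-compatible stand-in so variant calling, synonymy
    classification and simulation are exercised on realistic structure.
    """
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(_BASES), size=length))


@lru_cache(maxsize=2)
def synthetic_annotation(length: int = RCRS_LENGTH) -> Annotation:
    return default_annotation(synthetic_reference(length))


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions; ``seed`` is mandatory for reproducibility."""

    seed: int
    n_samples: int = 20
    effective_size: float = 1000.0  # female Ne
    generation_years: float = 25.0
    growth_rate: float = 0.0  # per generation, backwards-exponential
    substitution_rate: float = 1.0 / 3624.0  # per lineage per year
    genome_length: int = RCRS_LENGTH
    masked_positions: frozenset[int] = frozenset()
    scenario: str = "panmictic"  # | source_sink | island_pair
    fragment_range: tuple[int, int] | None = None
    synonymous_fraction: float | None = None
    # source/sink scenario
    founder_time_years: float | None = None
    n_founders: int = 1
    n_source: int | None = None
    n_sink: int | None = None
    sink_effective_size: float | None = None
    source_region: str = "Central"
    sink_region: str = "Eastern"
    # island pair scenario
    divergence: float = 0.0

    def __post_init__(self):
        if self.seed is None:
            raise SimulationError("seed is mandatory")
        if self.n_samples < 2:
            raise SimulationError("need at least 2 samples")
        if self.effective_size <= 0 or self.generation_years <= 0:
            raise SimulationError("sizes and generation time must be positive")
        if self.substitution_rate < 0:
            raise SimulationError("negative substitution rate")
        if self.scenario not in ("panmictic", "source_sink", "island_pair"):
            raise SimulationError(f"unknown scenario {self.scenario!r}")
        if not 0.0 <= self.divergence <= 1.0:
            raise SimulationError("divergence must be in [0, 1]")

    @classmethod
    def founder_scenario(cls, seed: int, **overrides) -> "SimConfig":
        """Default HVS-I source/sink colonization scenario.

        A well-sampled source population (100 HVS-I lineages, Ne = 2500)
        seeds a sink region through one founder lineage at 11 ka (the
        Pleistocene/Holocene transition); 20 sink lineages are sampled.
        Mutations fall in the 276-bp HVS-I window at 1 substitution per
        20,180 years.
        """
        defaults = dict(
            scenario="source_sink",
            n_source=100,
            n_sink=20,
            n_samples=120,
            effective_size=2500.0,
            sink_effective_size=1000.0,
            founder_time_years=11000.0,
            n_founders=1,
            substitution_rate=1.0 / HVS1_YEARS_PER_SUB,
            fragment_range=(HVS1_START, HVS1_END),
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)

    @classmethod
    def island_scenario(cls, seed: int, divergence: float, n_per_pop: int = 30, **overrides) -> "SimConfig":
        """Paired HVS-I population samples with divergence knob d in [0, 1]."""
        defaults = dict(
            scenario="island_pair",
            n_samples=n_per_pop,
            effective_size=1500.0,
            substitution_rate=1.0 / HVS1_YEARS_PER_SUB,
            fragment_range=(HVS1_START, HVS1_END),
            divergence=divergence,
        )
        defaults.update(overrides)
        return cls(seed=seed, **defaults)


@dataclass
class SimResult:
    true_tree: PhyloNode
    true_tmrca_years: float
    haplotypes: list[Haplotype]
    regions: dict[str, str]
    founder_node_ids: list[str] = field(default_factory=list)
    founder_time_years: float | None = None


# ---------------------------------------------------------------------------
# genealogy
# ---------------------------------------------------------------------------

def _waiting_time(k: int, t: float, ne0: float, growth: float, rng) -> float:
    """Time to next coalescence for k lineages at time t (generations ago)."""
    pairs = k * (k - 1) / 2.0
    e = rng.exponential()
    if growth == 0.0:
        return 2.0 * ne0 * e / pairs
    # N(t) = ne0 * exp(-growth * t); integrate hazard pairs/(2 N(t))
    return math.log(math.exp(growth * t) + 2.0 * ne0 * growth * e / pairs) / growth - t


def _coalesce(
    lineages: list[tuple[PhyloNode, float]],
    ne0: float,
    growth: float,
    generation_years: float,
    rng,
    t_start: float,
    t_stop: float | None,
    id_prefix: str,
    counter: Iterable[int],
) -> tuple[list[tuple[PhyloNode, float]], float]:
    """Run the coalescent from t_start until one lineage or t_stop (generations)."""
    t = t_start
    lineages = list(lineages)
    while len(lineages) > 1:
        w = _waiting_time(len(lineages), t, ne0, growth, rng)
        if t_stop is not None and t + w > t_stop:
            t = t_stop
            break
        t += w
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        (a, ta), (b, tb) = lineages[i], lineages[j]
        parent = PhyloNode(f"{id_prefix}{next(counter)}")
        a.branch_years = (t - ta) * generation_years
        b.branch_years = (t - tb) * generation_years
        parent.add_child(a)
        parent.add_child(b)
        lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
        lineages.append((parent, t))
    return lineages, t


def simulate_genealogy(config: SimConfig, rng=None) -> tuple[PhyloNode, float]:
    """Clock-like panmictic Kingman genealogy; returns (root, TMRCA in years)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tips = [
        (PhyloNode(f"T{i}", tip_samples=[f"T{i}"]), 0.0) for i in range(config.n_samples)
    ]
    counter = iter(range(10**9))
    lineages, t = _coalesce(
        tips,
        config.effective_size,
        config.growth_rate,
        config.generation_years,
        rng,
        t_start=0.0,
        t_stop=None,
        id_prefix="A",
        counter=counter,
    )
    root, t_root = lineages[0]
    root.branch_years = 0.0
    return root, t_root * config.generation_years


def tree_tmrca_years(tree: PhyloNode) -> float:
    """Root-to-tip path length in years (identical for all tips: clock-like)."""
    depths: list[float] = []
    def walk(node, acc):
        acc += node.branch_years or 0.0
        if not node.children:
            depths.append(acc)
        for c in node.children:
            walk(c, acc)
    walk(tree, 0.0)
    lo, hi = min(depths), max(depths)
    if hi - lo > 1e-6 * max(hi, 1.0):
        raise SimulationError(f"tree is not clock-like: tip depths span [{lo}, {hi}]")
    return hi


# ---------------------------------------------------------------------------
# mutations
# ---------------------------------------------------------------------------

def drop_mutations(
    true_tree: PhyloNode,
    config: SimConfig,
    rng=None,
    regions: dict[str, str] | None = None,
    populations: dict[str, str] | None = None,
) -> list[Haplotype]:
    """Poisson infinite-sites mutations on the genealogy; labels tree edges.

    Each branch receives Poisson(rate x branch_years) substitutions at
    positions drawn without replacement from the unmasked site pool, so no
    position recurs within one replicate.  Synonymy is classified against
    the synthetic reference and packaged gene map; ``synonymous_fraction``
    rejection-samples positions to hit a target synonymous share.
    Returns Haplotype records for the tips (tree edges gain edge_variants).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    reference = synthetic_reference(config.genome_length)
    annotation = synthetic_annotation(config.genome_length)

    lo, hi = config.fragment_range if config.fragment_range else (1, config.genome_length)
    pool = [p for p in range(lo, hi + 1) if p not in config.masked_positions]
    rng.shuffle(pool)
    pool_iter = iter(pool)
    used = 0

    def draw_variant(want_synonymous: bool | None) -> Variant:
        nonlocal used
        for _ in range(500):
            try:
                pos = next(pool_iter)
            except StopIteration:
                raise SimulationError("more mutations than available sites")
            used += 1
            ref_b = reference[pos - 1]
            alts = [b for b in _BASES if b != ref_b]
            der = alts[int(rng.integers(3))]
            v = Variant(pos, ref_b, der, "substitution")
            syn = classify_synonymous(v, annotation)
            v = dc_replace(v, synonymous=syn)
            if want_synonymous is None:
                return v
            if want_synonymous and syn == "yes":
                return v
            if not want_synonymous and syn != "yes":
                return v
            # rejection: position stays consumed (infinite sites)
        raise SimulationError("could not satisfy synonymous_fraction target")

    def mutate(node: PhyloNode):
        if node.parent is not None:
            years = node.branch_years or 0.0
            k = int(rng.poisson(config.substitution_rate * years))
            vs = []
            for _ in range(k):
                want = None
                if config.synonymous_fraction is not None:
                    want = bool(rng.random() < config.synonymous_fraction)
                vs.append(draw_variant(want))
            node.edge_variants = vs
        for c in node.children:
            mutate(c)

    mutate(true_tree)

    haps = []
    for tip in true_tree.iter_tips():
        sid = tip.tip_samples[0] if tip.tip_samples else tip.node_id
        variants = frozenset(tip.variants_from_root())
        haps.append(
            Haplotype(
                sample_id=sid,
                population=(populations or {}).get(sid, "simulated"),
                region=(regions or {}).get(sid, "other"),
                variants=variants,
                covered_range=(lo, hi),
            )
        )
    return haps


def simulate_panmictic(config: SimConfig) -> SimResult:
    rng = np.random.default_rng(config.seed)
    tree, tmrca = simulate_genealogy(config, rng)
    haps = drop_mutations(tree, config, rng)
    regions = {h.sample_id: h.region for h in haps}
    return SimResult(tree, tmrca, haps, regions)


# ---------------------------------------------------------------------------
# source/sink colonization
# ---------------------------------------------------------------------------

def simulate_source_sink(config: SimConfig) -> SimResult:
    """Sink tips descend from ``n_founders`` lineages present at the founder time.

    Sink lineages coalesce among themselves (sink Ne) back to the founder
    time, are bottlenecked to the founder count, and each surviving founder
    lineage gets an explicit node planted at exactly founder_time_years;
    founders then join the source pool, which coalesces at the source Ne.
    """
    if config.scenario != "source_sink":
        raise SimulationError("config.scenario must be 'source_sink'")
    if not config.n_sink or config.n_sink < 1:
        raise SimulationError("source_sink scenario needs at least one sink sample")
    if not config.n_source or config.n_source < 1:
        raise SimulationError("source_sink scenario needs source samples")
    if config.founder_time_years is None or config.founder_time_years <= 0:
        raise SimulationError("founder_time_years must be positive")
    if not 1 <= config.n_founders <= config.n_sink:
        raise SimulationError("n_founders must be in [1, n_sink]")

    rng = np.random.default_rng(config.seed)
    gen = config.generation_years
    t_f = config.founder_time_years / gen
    sink_ne = config.sink_effective_size or config.effective_size
    counter = iter(range(10**9))

    sink_tips = [
        (PhyloNode(f"S{i}", tip_samples=[f"S{i}"]), 0.0) for i in range(config.n_sink)
    ]
    source_tips = [
        (PhyloNode(f"C{i}", tip_samples=[f"C{i}"]), 0.0) for i in range(config.n_source)
    ]

    sink_lineages, _ = _coalesce(
        sink_tips, sink_ne, 0.0, gen, rng, 0.0, t_f, "A", counter
    )
    # founding bottleneck: force down to n_founders at the founder time
    while len(sink_lineages) > config.n_founders:
        i, j = sorted(rng.choice(len(sink_lineages), size=2, replace=False))
        (a, ta), (b, tb) = sink_lineages[i], sink_lineages[j]
        parent = PhyloNode(f"A{next(counter)}")
        a.branch_years = (t_f - ta) * gen
        b.branch_years = (t_f - tb) * gen
        parent.add_child(a)
        parent.add_child(b)
        sink_lineages = [l for k, l in enumerate(sink_lineages) if k not in (i, j)]
        sink_lineages.append((parent, t_f))

    source_lineages, _ = _coalesce(
        source_tips, config.effective_size, config.growth_rate, gen, rng, 0.0, t_f, "A", counter
    )
    if config.n_founders > len(source_lineages):
        raise SimulationError("fewer source lineages at the founder time than n_founders")

    # the migrating lineage is a source lineage at the founder time: each
    # founder node joins the sink clade onto a sampled source lineage at t_f,
    # so the founder haplotype is carried by source ancestry by construction
    chosen = rng.choice(len(source_lineages), size=config.n_founders, replace=False)
    founder_ids = []
    founders = []
    for idx, (sink_node, t0) in enumerate(sink_lineages):
        src_node, t_src = source_lineages[int(chosen[idx])]
        f = PhyloNode(f"F{idx}")
        sink_node.branch_years = (t_f - t0) * gen
        src_node.branch_years = (t_f - t_src) * gen
        f.add_child(sink_node)
        f.add_child(src_node)
        founder_ids.append(f.node_id)
        founders.append((f, t_f))
    remaining = [
        l for i, l in enumerate(source_lineages) if i not in set(int(c) for c in chosen)
    ]
    pool = remaining + founders
    lineages, t_root = _coalesce(
        pool, config.effective_size, config.growth_rate, gen, rng, t_f, None, "A", counter
    )
    root, t_root = lineages[0]
    root.branch_years = 0.0
    tmrca = t_root * gen

    regions = {f"S{i}": config.sink_region for i in range(config.n_sink)}
    regions.update({f"C{i}": config.source_region for i in range(config.n_source)})
    populations = {s: ("sink_pop" if s.startswith("S") else "source_pop") for s in regions}
    haps = drop_mutations(root, config, rng, regions=regions, populations=populations)
    return SimResult(
        root,
        tmrca,
        haps,
        regions,
        founder_node_ids=founder_ids,
        founder_time_years=config.founder_time_years,
    )


# ---------------------------------------------------------------------------
# island pair
# ---------------------------------------------------------------------------

def simulate_island_pair(config: SimConfig) -> tuple[PopulationSample, PopulationSample]:
    """Two HVS-I population samples with divergence knob d.

    d = 0: both populations draw from one shared haplotype distribution
    (derived from a panmictic coalescent sample).  d > 0: each individual is
    instead, with probability d, a population-private haplotype (the shared
    modal haplotype plus private diagnostic mutations), so d = 1 gives two
    samples fixed for different haplotypes and FST = 1.
    """
    if config.scenario != "island_pair":
        raise SimulationError("config.scenario must be 'island_pair'")
    rng = np.random.default_rng(config.seed)
    d = config.divergence
    n = config.n_samples

    pool_cfg = dc_replace(config, scenario="panmictic", n_samples=max(2 * n, 40))
    tree, _ = simulate_genealogy(pool_cfg, rng)
    pool_haps = drop_mutations(tree, pool_cfg, rng)
    pool_sets = [h.variants for h in pool_haps]

    # modal shared haplotype as the base for private types
    from collections import Counter

    base = Counter(pool_sets).most_common(1)[0][0]
    lo, hi = config.fragment_range if config.fragment_range else (1, config.genome_length)
    used = {v.position for s in pool_sets for v in s}
    free = [p for p in range(lo, hi + 1) if p not in used and p not in config.masked_positions]
    rng.shuffle(free)
    if len(free) < 6:
        raise SimulationError("not enough free sites for private haplotypes")
    reference = synthetic_reference(config.genome_length)

    def private(positions):
        vs = set(base)
        for p in positions:
            ref_b = reference[p - 1]
            alts = [b for b in _BASES if b != ref_b]
            vs.add(Variant(p, ref_b, alts[int(rng.integers(3))], "substitution"))
        return frozenset(vs)

    private_a = private(free[:3])
    private_b = private(free[3:6])

    def sample_members(prefix: str, popname: str, private_set) -> list[Haplotype]:
        members = []
        for i in range(n):
            if rng.random() < d:
                vs = private_set
            else:
                vs = pool_sets[int(rng.integers(len(pool_sets)))]
            members.append(
                Haplotype(
                    sample_id=f"{prefix}{i}",
                    population=popname,
                    region="other",
                    variants=vs,
                    covered_range=(lo, hi),
                )
            )
        return members

    pop_a = PopulationSample("island_A", sample_members("IA", "island_A", private_a))
    pop_b = PopulationSample("island_B", sample_members("IB", "island_B", private_b))
    return pop_a, pop_b


# ---------------------------------------------------------------------------
# writers: the pipeline's input dialects plus truth files
# ---------------------------------------------------------------------------

def write_reference_fasta(path, length: int = RCRS_LENGTH) -> None:
    ref = synthetic_reference(length)
    with open(path, "w") as fh:
        fh.write(">synthetic_reference\n")
        for i in range(0, len(ref), 70):
            fh.write(ref[i : i + 70] + "\n")


def write_fasta(haplotypes: list[Haplotype], path, reference: str | None = None) -> None:
    """Reconstruct full sequences from variants and write FASTA (substitutions only)."""
    if reference is None:
        reference = synthetic_reference()
    with open(path, "w") as fh:
        for h in haplotypes:
            lo, hi = h.covered_range
            seq = apply_variants(
                reference, [v for v in h.variants if v.var_class == "substitution"]
            )[lo - 1 : hi]
            fh.write(f">{h.sample_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_metadata_tsv(haplotypes: list[Haplotype], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tpopulation\tregion\n")
        for h in haplotypes:
            fh.write(f"{h.sample_id}\t{h.population}\t{h.region}\n")


def write_truth_json(result: SimResult, path) -> None:
    payload = {
        "true_tmrca_years": result.true_tmrca_years,
        "founder_node_ids": result.founder_node_ids,
        "founder_time_years": result.founder_time_years,
        "n_samples": len(result.haplotypes),
        "regions": result.regions,
        "newick": to_newick(result.true_tree, include_variants=True),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
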