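"""Founder analysis: dating migrations from sink-region lineages.

A migration into a sink region is dated by computing the rho statistic of a
designated founder node over the *sink-region tips only*: the mean number of
mutations accumulated by sink lineages since the founder haplotype entered
the region estimates the arrival time under a molecular clock (typically a
fragment-scaled HVS-I clock).  Founder nodes are user-designated, or
proposed heuristically by ``scan_founder_candidates``: nodes whose own
haplotype state is observed in (or ancestral to) source-region tips and
which subtend enough sink-region lineages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .dating import Clock, DatingError, RhoEstimate, _counter, _edge_stats, age_estimate, _locate
from .network import PhyloNode


class FounderError(ValueError):
    pass


@dataclass(frozen=True)
class FounderResult:
    founder_node_id: str
    sink_region: str
    n_sink_tips: int
    rho_estimate: RhoEstimate


def _sink_weight(regions: Mapping[str, str], sink_region: str):
    def weight(tip: PhyloNode) -> int:
        return sum(1 for s in tip.tip_samples if regions.get(s) == sink_region)

    return weight


def founder_age(
    tree: PhyloNode,
    founder_node,
    sink_region: str,
    clock: Clock,
    regions: Mapping[str, str],
) -> FounderResult:
    """Rho age of a founder node computed over sink-region tips only.

    ``regions`` maps sample_id -> region label.  Identical to plain clade
    dating when every tip below the node is in the sink region.
    """
    target = _locate(tree, founder_node)
    count = _counter(clock.counting_rule, clock.fragment_range)
    n, stats = _edge_stats(target, count, tip_weight=_sink_weight(regions, sink_region))
    if n == 0:
        raise FounderError(
            f"no {sink_region!r} tips below node {target.node_id!r}"
        )
    rho = sum(m * k for m, k in stats) / n
    sigma = (sum((k / n) ** 2 * m for m, k in stats)) ** 0.5
    est = age_estimate(rho, sigma, clock, n, node_id=target.node_id)
    return FounderResult(
        founder_node_id=target.node_id,
        sink_region=sink_region,
        n_sink_tips=n,
        rho_estimate=est,
    )


def scan_founder_candidates(
    tree: PhyloNode,
    source_region: str,
    sink_region: str,
    regions: Mapping[str, str],
    min_sink_tips: int = 3,
) -> list[str]:
    """Heuristic founder-node proposal.

    A candidate's haplotype state must be observed in, or ancestral to, a
    source-region tip — i.e. its root-to-node variant set is contained in
    some source tip's variant set — and it must subtend at least
    ``min_sink_tips`` sink-region tips.  Sorted by sink tip count
    (descending), then node id.
    """
    source_tip_sets = []
    for tip in tree.iter_tips():
        if any(regions.get(s) == source_region for s in tip.tip_samples):
            source_tip_sets.append({str(v) for v in tip.variants_from_root()})

    candidates = []
    for node in tree.iter_nodes():
        n_sink = sum(
            sum(1 for s in t.tip_samples if regions.get(s) == sink_region)
            for t in node.iter_tips()
        )
        if n_sink < min_sink_tips:
            continue
        state = {str(v) for v in node.variants_from_root()}
        if any(state <= src for src in source_tip_sets):
            candidates.append((n_sink, node.node_id))
    candidates.sort(key=lambda t: (-t[0], t[1]))
    return [node_id for _, node_id in candidates]


def founder_report(
    tree: PhyloNode,
    founder_nodes,
    sink_region: str,
    clock: Clock,
    regions: Mapping[str, str],
) -> pd.DataFrame:
    rows = []
    for node in founder_nodes:
        res = founder_age(tree, node, sink_region, clock, regions)
        est = res.rho_estimate
        rows.append(
            {
                "node": res.founder_node_id,
                "sink_region": sink_region,
                "n_sink": res.n_sink_tips,
                "rho": est.rho,
                "sigma": est.sigma,
                "age_years": est.age_years,
                "ci_low": est.ci95[0],
                "ci_high": est.ci95[1],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["node", "sink_region", "n_sink", "rho", "sigma", "age_years", "ci_low", "ci_high"],
    )
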