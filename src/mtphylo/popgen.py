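"""HVS-I population comparison: FST, permutation tests, MDS, composition.

Pairwise FST between population samples of control-region haplotypes is the
AMOVA fixation index (between-population variance component over total),
computed from a molecular distance matrix — haplotype identity (0/1) by
default, or pairwise position differences for a PhiST-like index.
Significance comes from permuting individuals between the two samples;
p-values are Bonferroni-corrected.  Slatkin's linearization FST/(1-FST)
turns the index into a distance roughly linear in divergence time, ordinated
by metric MDS minimizing Young's S-stress (squared-distance stress).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .sequence_io import Haplotype


class PopgenError(ValueError):
    pass


@dataclass
class PopulationSample:
    """A named population of haplotypes restricted to one analysis fragment."""

    name: str
    members: list[Haplotype]
    country: str = ""
    language: str = ""

    def __post_init__(self):
        if not self.members:
            raise PopgenError(f"population {self.name!r} is empty")
        ranges = {h.covered_range for h in self.members}
        if len(ranges) != 1:
            raise PopgenError(f"population {self.name!r} mixes covered ranges {ranges}")

    @property
    def covered_range(self) -> tuple[int, int]:
        return self.members[0].covered_range

    def __len__(self):
        return len(self.members)


@dataclass
class PopDistanceMatrix:
    names: list[str]
    fst: pd.DataFrame
    p_values: pd.DataFrame
    linearized: pd.DataFrame


@dataclass
class MdsResult:
    coordinates: np.ndarray  # populations x k, centered at the origin
    s_stress: float


# ---------------------------------------------------------------------------
# distances and AMOVA FST
# ---------------------------------------------------------------------------

def _variant_keys(h: Haplotype) -> frozenset:
    return frozenset((v.position, v.insertion_index, v.derived_base) for v in h.variants)


def squared_distance_matrix(
    members: Sequence[Haplotype], distance_mode: str = "haplotype_identity"
) -> np.ndarray:
    """Squared molecular distances between individuals.

    ``haplotype_identity``: 0 if identical, 1 otherwise (conventional FST
    from haplotype frequencies).  ``pairwise_differences``: number of
    differing positions (PhiST-like).
    """
    keys = [_variant_keys(h) for h in members]
    n = len(keys)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if distance_mode == "haplotype_identity":
                d = 0.0 if keys[i] == keys[j] else 1.0
            elif distance_mode == "pairwise_differences":
                d = float(len(keys[i] ^ keys[j]))
            else:
                raise PopgenError(f"unknown distance mode {distance_mode!r}")
            D[i, j] = D[j, i] = d
    return D


def _fst_from_sqdist(D: np.ndarray, labels: np.ndarray) -> float:
    """AMOVA fixation index from a squared-distance matrix and group labels."""
    N = len(labels)
    groups = np.unique(labels)
    P = len(groups)
    ssd_total = D.sum() / (2 * N)
    ssd_within = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sizes.append(len(idx))
        ssd_within += D[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_among = P - 1
    df_within = N - P
    ms_within = ssd_within / df_within if df_within > 0 else 0.0
    sizes = np.array(sizes, dtype=float)
    n_prime = (N - (sizes**2).sum() / N) / df_among
    sigma_among = (ssd_among / df_among - ms_within) / n_prime
    total = sigma_among + ms_within
    if total == 0:
        return 0.0
    return sigma_among / total


def pairwise_fst(
    popA: PopulationSample,
    popB: PopulationSample,
    distance_mode: str = "haplotype_identity",
) -> float:
    if popA.covered_range != popB.covered_range:
        raise PopgenError("populations cover different fragments")
    members = popA.members + popB.members
    D = squared_distance_matrix(members, distance_mode)
    labels = np.array([0] * len(popA) + [1] * len(popB))
    return _fst_from_sqdist(D, labels)


def permutation_pvalue(
    popA: PopulationSample,
    popB: PopulationSample,
    n_permutations: int = 10000,
    seed: int | None = None,
    distance_mode: str = "haplotype_identity",
) -> float:
    """Permutation p-value: random reassignment of individuals to samples.

    p = (1 + #{permuted FST >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise PopgenError("need at least one permutation")
    if popA.covered_range != popB.covered_range:
        raise PopgenError("populations cover different fragments")
    members = popA.members + popB.members
    D = squared_distance_matrix(members, distance_mode)
    labels = np.array([0] * len(popA) + [1] * len(popB))
    observed = _fst_from_sqdist(D, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(len(labels))
        if _fst_from_sqdist(D[np.ix_(perm, perm)], labels) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (n_permutations + 1)


def bonferroni(p_values: Sequence[float], alpha: float = 0.05) -> np.ndarray:
    """Significance flags under Bonferroni: p_i <= alpha / m."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise PopgenError("no tests")
    return p <= alpha / p.size


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearized FST, FST/(1-FST); negatives floored at 0 first."""
    if fst >= 1:
        raise PopgenError("linearized FST undefined at FST = 1")
    fst = max(0.0, fst)
    return fst / (1.0 - fst)


def fst_matrix(
    populations: Sequence[PopulationSample],
    n_permutations: int = 10000,
    seed: int | None = None,
    distance_mode: str = "haplotype_identity",
) -> PopDistanceMatrix:
    """All pairwise FST, permutation p-values and linearized distances."""
    names = [p.name for p in populations]
    k = len(populations)
    fst = np.zeros((k, k))
    pvals = np.ones((k, k))
    lin = np.zeros((k, k))
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            f = pairwise_fst(populations[i], populations[j], distance_mode)
            p = permutation_pvalue(
                populations[i],
                populations[j],
                n_permutations,
                seed=int(rng.integers(2**31 - 1)),
                distance_mode=distance_mode,
            )
            fst[i, j] = fst[j, i] = f
            pvals[i, j] = pvals[j, i] = p
            l = slatkin_linearize(min(f, 1 - 1e-12))
            lin[i, j] = lin[j, i] = l
    assert np.allclose(fst, fst.T)
    mk = lambda a: pd.DataFrame(a, index=names, columns=names)
    return PopDistanceMatrix(names, mk(fst), mk(pvals), mk(lin))


def merge_nonsignificant(
    populations: Sequence[PopulationSample],
    merge_candidates: Sequence[Sequence[str]],
    alpha: float = 0.05,
    n_permutations: int = 10000,
    seed: int | None = None,
    distance_mode: str = "haplotype_identity",
) -> list[PopulationSample]:
    """Pool candidate populations whose pairwise FST is non-significant.

    ``merge_candidates`` lists groups eligible for pooling (same ethnic
    group across countries/studies, or same country).  Within each group,
    populations connected by non-significant (Bonferroni-corrected) FST are
    merged into one sample; everything else is left intact.
    """
    by_name = {p.name: p for p in populations}
    tests = []  # (groupidx, nameA, nameB, p)
    rng = np.random.default_rng(seed)
    for gi, group in enumerate(merge_candidates):
        for a_i in range(len(group)):
            for b_i in range(a_i + 1, len(group)):
                a, b = group[a_i], group[b_i]
                p = permutation_pvalue(
                    by_name[a], by_name[b], n_permutations,
                    seed=int(rng.integers(2**31 - 1)), distance_mode=distance_mode,
                )
                tests.append((a, b, p))
    if not tests:
        return list(populations)
    flags = bonferroni([t[2] for t in tests], alpha)

    # union-find over non-significant pairs
    parent = {p.name: p.name for p in populations}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b, _), significant in zip(tests, flags):
        if not significant:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[PopulationSample]] = {}
    order: list[str] = []
    for p in populations:
        r = find(p.name)
        if r not in clusters:
            clusters[r] = []
            order.append(r)
        clusters[r].append(p)
    merged = []
    for r in order:
        group = clusters[r]
        if len(group) == 1:
            merged.append(group[0])
        else:
            name = "+".join(sorted(g.name for g in group))
            members = [h for g in group for h in g.members]
            merged.append(PopulationSample(name=name, members=members, country=group[0].country))
    return merged


# ---------------------------------------------------------------------------
# multidimensional scaling with S-stress
# ---------------------------------------------------------------------------

def _s_stress(X: np.ndarray, S: np.ndarray, denom: float) -> tuple[float, np.ndarray]:
    """Normalized S-stress^2 and its gradient; S holds target squared distances."""
    diff = X[:, None, :] - X[None, :, :]
    D2 = (diff**2).sum(axis=2)
    R = D2 - S
    np.fill_diagonal(R, 0.0)
    f = (R**2).sum() / denom
    grad = 8.0 * (R[:, :, None] * diff).sum(axis=1) / denom
    return f, grad


def mds(distances, k: int = 2) -> MdsResult:
    """Metric MDS minimizing Young's S-stress.

    ``distances`` is a symmetric zero-diagonal matrix of (linearized)
    distances.  Initialization is classical (eigen-decomposition) scaling;
    the configuration is then refined by quasi-Newton descent on the
    squared-distance stress

        S-stress = sqrt( sum_{i<j} (d_ij^2 - delta_ij^2)^2 / sum delta_ij^4 ).
    """
    if isinstance(distances, pd.DataFrame):
        D = distances.to_numpy(dtype=float)
    else:
        D = np.asarray(distances, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise PopgenError("need a symmetric zero-diagonal distance matrix")
    if k >= n:
        raise PopgenError("k must be smaller than the number of populations")

    S = D**2
    denom = (S**2).sum()
    if denom == 0:
        return MdsResult(np.zeros((n, k)), 0.0)

    # classical scaling start
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ S @ J
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:k]
    X0 = vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))

    res = minimize(
        lambda x: _s_stress(x.reshape(n, k), S, denom),
        X0.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-12},
    )
    X = res.x.reshape(n, k)
    X = X - X.mean(axis=0)
    f, _ = _s_stress(X, S, denom)
    return MdsResult(X, float(np.sqrt(max(f, 0.0))))


# ---------------------------------------------------------------------------
# haplogroup composition
# ---------------------------------------------------------------------------

def _motif_key(entry) -> str:
    return str(entry)


def classify_lineage(hap: Haplotype, motif_classifier: Mapping[str, Iterable]) -> str:
    """Assign a haplogroup label from HVS-I motifs.

    A label matches when every motif variant is carried.  The most specific
    (largest-motif, then longest-named) label wins; a haplotype whose best
    match has defined subclades but matches none of them is reported with a
    ``*`` suffix (e.g. ``L2*``, the convention for L2 lineages that HVS-I
    cannot place in a subclade).  Matching two disjoint top-level labels is
    an error (inconsistent classifier).
    """
    keys = {f"{v.position}{v.derived_base}" for v in hap.variants}
    motifs = {label: {_motif_key(m) for m in ms} for label, ms in motif_classifier.items()}
    matches = [label for label, ms in motifs.items() if ms <= keys]
    if not matches:
        return "other"
    top_level = [l for l in motifs if not any(l != o and l.startswith(o) for o in motifs)]
    top_matches = {l for l in matches if l in top_level}
    for a in sorted(top_matches):
        for b in sorted(top_matches):
            if a < b and not a.startswith(b) and not b.startswith(a):
                raise PopgenError(
                    f"haplotype {hap.sample_id!r} matches disjoint top-level labels {a!r}, {b!r}"
                )
    best = max(matches, key=lambda l: (len(motifs[l]), len(l), l))
    children = [l for l in motifs if l != best and l.startswith(best)]
    if children and not any(c in matches for c in children):
        return best + "*"
    return best


def haplogroup_composition(
    populations: Sequence[PopulationSample],
    motif_classifier: Mapping[str, Iterable],
    by: str = "population",
) -> pd.DataFrame:
    """Per-population (or per-region) haplogroup frequency table; rows sum to 1."""
    counts: dict[str, dict[str, int]] = {}
    for pop in populations:
        for h in pop.members:
            key = pop.name if by == "population" else h.region
            label = classify_lineage(h, motif_classifier)
            counts.setdefault(key, {}).setdefault(label, 0)
            counts[key][label] += 1
    labels = sorted({l for row in counts.values() for l in row})
    rows = []
    for key in sorted(counts):
        total = sum(counts[key].values())
        rows.append({"group": key, **{l: counts[key].get(l, 0) / total for l in labels}})
    return pd.DataFrame(rows, columns=["group", *labels]).set_index("group")


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def plot_mds(result: MdsResult, names: Sequence[str], path) -> None:
    """Optional scatter plot of the first two MDS dimensions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    X = result.coordinates
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(X[:, 0], X[:, 1], s=12)
    for name, (x, y) in zip(names, X[:, :2]):
        ax.annotate(name, (x, y), fontsize=7)
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_title(f"MDS (S-stress = {result.s_stress:.3g})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
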