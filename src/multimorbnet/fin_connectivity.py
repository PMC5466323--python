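"""Topological-overlap connectivity of disease protein sets on the FIN.

The topological overlap (TO) between nodes *a* and *b* is

    TO(a, b) = (|N(a) ∩ N(b)| + adj(a, b)) / min(|N(a)|, |N(b)|)

where |N(a) ∩ N(b)| counts *third-party* neighbors common to both nodes,
adj(a, b) is 1 when the edge {a, b} exists and 0 otherwise, and the
denominator is the smaller degree.  TO is symmetric and lies in [0, 1]:
0 when the nodes are not adjacent and share no neighbors, 1 when one
neighborhood is contained in the other (adjacency included in the
bookkeeping).

Mean TO is computed either over all pairs of proteins *common* to a disease
combination, or over cross-disease pairs of proteins *unique* to each
disease.  The null model exchanges disease proteins for random FIN proteins
of the same connectivity bin, round(ln(d) + 1), while preserving every
per-disease count and every intersection cell exactly.

Edge-level overlap treats an edge as associated to a disease when at least
one endpoint is; the per-disease edge sets are then compared with the
Jaccard index.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator, Sequence

import networkx as nx
import numpy as np

from .io_formats import DiseaseProteinSet, edge_key
from .overlap_stats import NullDistribution

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TopologicalOverlapResult:
    pair_values: dict[tuple[str, str], float]
    mean_to: float | None
    group_spec: str
    note: str = ""

    @property
    def computable(self) -> bool:
        return self.mean_to is not None


@dataclass(frozen=True)
class EdgeOverlapResult:
    diseases: tuple[str, ...]
    edge_counts: dict[str, int]
    unique_edge_counts: dict[str, int]
    common_edges: int
    union_edges: int
    jaccard: float


def topological_overlap(G: nx.Graph, a: str, b: str) -> float:
    """TO between two distinct nodes of ``G``; symmetric, in [0, 1]."""
    if a not in G or b not in G:
        missing = a if a not in G else b
        raise ValueError(f"node {missing!r} absent from the network")
    if a == b:
        raise ValueError("topological overlap requires two distinct nodes")
    na = set(G[a])
    nb = set(G[b])
    deg_a, deg_b = len(na), len(nb)
    if deg_a == 0 or deg_b == 0:
        raise ValueError("topological overlap undefined for degree-0 nodes")
    adjacent = 1 if b in na else 0
    common = len((na & nb) - {a, b})
    return (common + adjacent) / min(deg_a, deg_b)


def _usable_nodes(G: nx.Graph, proteins: frozenset[str]) -> set[str]:
    """Proteins that are FIN nodes of degree >= 1; the rest are dropped."""
    kept = {p for p in proteins if p in G and G.degree(p) >= 1}
    dropped = len(proteins) - len(kept)
    if dropped:
        logger.info("dropped %d protein(s) absent from the FIN or of degree 0", dropped)
    return kept


def _mean_pairs(G: nx.Graph, pairs: list[tuple[str, str]], group_spec: str,
                note: str = "") -> TopologicalOverlapResult:
    values = {
        (min(x, y), max(x, y)): topological_overlap(G, x, y) for x, y in pairs
    }
    mean = float(np.mean(list(values.values()))) if values else None
    return TopologicalOverlapResult(values, mean, group_spec, note)


def mean_to_common(
    G: nx.Graph, sets: Sequence[DiseaseProteinSet]
) -> TopologicalOverlapResult:
    """Mean TO over all pairs of proteins common to every disease in ``sets``."""
    if len(sets) < 2:
        raise ValueError("need at least two disease sets")
    common = frozenset.intersection(*[s.proteins for s in sets])
    usable = sorted(_usable_nodes(G, common))
    spec = "common:" + "+".join(s.name for s in sets)
    if len(usable) < 2:
        return TopologicalOverlapResult(
            {}, None, spec,
            note=f"not computable: only {len(usable)} common protein(s) in the FIN",
        )
    pairs = list(itertools.combinations(usable, 2))
    return _mean_pairs(G, pairs, spec)


def unique_sets(sets: Sequence[DiseaseProteinSet]) -> list[frozenset[str]]:
    """Per-disease proteins not associated with any other disease in ``sets``."""
    out = []
    for i, s in enumerate(sets):
        other_sets = [t.proteins for j, t in enumerate(sets) if j != i]
        others = frozenset.union(*other_sets) if other_sets else frozenset()
        out.append(s.proteins - others)
    return out


def mean_to_unique(
    G: nx.Graph,
    sets: Sequence[DiseaseProteinSet],
    mode: str = "cross",
) -> TopologicalOverlapResult:
    """Mean TO over proteins unique to each disease.

    ``mode="cross"`` (default) averages over pairs (x, y) with x unique to
    disease i and y unique to disease j, i < j.  ``mode="within"`` averages
    over pairs inside each disease's own unique set (pass a single set to get
    the one-disease variant).
    """
    if mode not in ("cross", "within"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "cross" and len(sets) < 2:
        raise ValueError("cross mode needs at least two disease sets")
    uniq = [sorted(_usable_nodes(G, u)) for u in unique_sets(sets)]
    spec = f"unique-{mode}:" + "+".join(s.name for s in sets)
    if mode == "cross":
        if any(not u for u in uniq):
            empty = [s.name for s, u in zip(sets, uniq) if not u]
            return TopologicalOverlapResult(
                {}, None, spec,
                note=f"not computable: no unique FIN proteins for {empty}",
            )
        pairs = [
            (x, y)
            for i, j in itertools.combinations(range(len(uniq)), 2)
            for x in uniq[i]
            for y in uniq[j]
        ]
    else:
        pairs = [
            (x, y) for u in uniq for x, y in itertools.combinations(u, 2)
        ]
        if not pairs:
            return TopologicalOverlapResult(
                {}, None, spec, note="not computable: fewer than 2 unique proteins"
            )
    return _mean_pairs(G, pairs, spec)


def degree_bin(d: int) -> int:
    """Connectivity bin round(ln(d) + 1), with round-half-to-even."""
    if d < 1:
        raise ValueError("degree must be >= 1")
    return round(math.log(d) + 1)


def binned_swap_replicates(
    G: nx.Graph,
    sets: Sequence[DiseaseProteinSet],
    R: int = 1_000,
    seed: int | None = None,
) -> Iterator[list[DiseaseProteinSet]]:
    """Yield R randomized versions of ``sets`` under the binned node swap.

    Every disease protein (restricted to FIN nodes of degree >= 1) is replaced
    by a uniformly chosen FIN node from the same connectivity bin, injectively
    within a replicate, so per-disease counts and all intersection cells are
    preserved exactly.
    """
    rng = np.random.default_rng(seed)
    restricted = [frozenset(_usable_nodes(G, s.proteins)) for s in sets]
    union = sorted(frozenset.union(*restricted)) if restricted else []
    # membership signature -> cell of nodes; preserved under the injective remap
    bins: dict[int, list[str]] = {}
    for node in G.nodes:
        d = G.degree(node)
        if d >= 1:
            bins.setdefault(degree_bin(d), []).append(node)
    for b in bins.values():
        b.sort()
    node_bin = {n: degree_bin(G.degree(n)) for n in union}

    for _ in range(R):
        mapping: dict[str, str] = {}
        used: set[str] = set()
        for node in union:
            b = node_bin[node]
            pool = bins[b]
            choice = None
            if len(pool) > 2 * len(used):
                # large pool: rejection sampling, still uniform over unused
                for _ in range(64):
                    cand = pool[int(rng.integers(len(pool)))]
                    if cand not in used:
                        choice = cand
                        break
            if choice is None:
                candidates = [c for c in pool if c not in used]
                if not candidates:
                    raise ValueError(
                        f"connectivity bin {b} exhausted: no replacement left for {node!r}"
                    )
                choice = candidates[int(rng.integers(len(candidates)))]
            mapping[node] = choice
            used.add(choice)
        yield [
            DiseaseProteinSet(s.name, frozenset(mapping[p] for p in r))
            for s, r in zip(sets, restricted)
        ]


def binned_swap_null(
    G: nx.Graph,
    sets: Sequence[DiseaseProteinSet],
    statistic: Callable[[nx.Graph, Sequence[DiseaseProteinSet]], float],
    R: int = 1_000,
    seed: int | None = None,
) -> NullDistribution:
    """Null distribution of ``statistic(G, randomized_sets)`` under the swap."""
    samples = np.array(
        [statistic(G, reps) for reps in binned_swap_replicates(G, sets, R, seed)],
        dtype=float,
    )
    return NullDistribution(
        statistic_name=getattr(statistic, "__name__", "statistic"),
        samples=samples,
        method="binned_node_swap",
        seed=seed,
    )


def disease_edges(G: nx.Graph, disease: DiseaseProteinSet) -> frozenset[tuple[str, str]]:
    """Edges with at least one endpoint associated to the disease."""
    proteins = disease.proteins
    return frozenset(
        edge_key(u, v)
        for p in proteins
        if p in G
        for u, v in G.edges(p)
    )


def edge_disease_overlap(
    G: nx.Graph, sets: Sequence[DiseaseProteinSet]
) -> EdgeOverlapResult:
    """Per-disease edge counts and the Jaccard overlap of the edge sets."""
    if len(sets) < 2:
        raise ValueError("need at least two disease sets")
    per = {s.name: disease_edges(G, s) for s in sets}
    common = frozenset.intersection(*per.values())
    union = frozenset.union(*per.values())
    unique = {
        name: len(e - frozenset.union(*[o for n, o in per.items() if n != name]))
        for name, e in per.items()
    }
    return EdgeOverlapResult(
        diseases=tuple(s.name for s in sets),
        edge_counts={n: len(e) for n, e in per.items()},
        unique_edge_counts=unique,
        common_edges=len(common),
        union_edges=len(union),
        jaccard=len(common) / len(union) if union else 0.0,
    )
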