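"""Guilt-by-association prediction of new disease proteins by network
propagation, z-scored against degree-preserving random networks.

The scorer follows the NetZcore scheme: seed nodes (experimentally known
disease proteins) start with score 1, all other nodes with 0, on the real
network and on R rewired networks sharing its exact degree sequence.  Each
iteration every node's raw value is the mean of its neighbors' current
scores; on the real network the node's score is then replaced by the z-score
of its raw value against the distribution of raw values the node attains on
the random networks, which keep propagating their own raw scores.  After a
fixed number of iterations (5 by default) the per-node z-scores are returned;
nodes whose null is degenerate (sd = 0, e.g. when every node is a seed) are
scored 0 and flagged.

Random networks are produced by repeated double-edge swaps: two edges
(a, b), (c, d) are replaced by (a, d), (c, b) unless that would create a
self-loop or duplicate edge.  Degree sequences are conserved exactly.

A candidate is called for a disease when its z-score exceeds 2.31
(one-sided P < 0.01); proteins called or already known for two or more
diseases are multimorbidity candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numba
import numpy as np
import pandas as pd
from scipy import sparse

from .io_formats import DiseaseProteinSet, edge_key

logger = logging.getLogger(__name__)

Z_THRESHOLD = 2.31  # one-sided P < 0.01
DEFAULT_ITERATIONS = 5
DEFAULT_SWAPS_PER_EDGE = 100


@dataclass(frozen=True)
class PropagationResult:
    disease_name: str
    seed_nodes: frozenset[str]
    scores: dict[str, float]
    degenerate: frozenset[str]
    iterations: int
    R_networks: int
    threshold: float = Z_THRESHOLD

    def called(self) -> frozenset[str]:
        """Non-seed nodes scoring strictly above the threshold."""
        return frozenset(
            n for n, z in self.scores.items()
            if z > self.threshold and n not in self.seed_nodes
        )


@numba.njit(cache=True)
def _swap_kernel(ea, eb, n, idx, flip):  # pragma: no cover - exercised via random_rewire
    edge_set = numba.typed.Dict.empty(numba.int64, numba.uint8)
    for k in range(len(ea)):
        edge_set[ea[k] * n + eb[k]] = numba.uint8(1)
    for t in range(idx.shape[0]):
        i = idx[t, 0]
        j = idx[t, 1]
        if i == j:
            continue
        a = ea[i]
        b = eb[i]
        c = ea[j]
        d = eb[j]
        if flip[t]:
            tmp = c
            c = d
            d = tmp
        if a == d or c == b:
            continue  # proposal would create a self-loop
        e1 = a * n + d if a < d else d * n + a
        e2 = c * n + b if c < b else b * n + c
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        del edge_set[ea[i] * n + eb[i]]
        del edge_set[ea[j] * n + eb[j]]
        edge_set[e1] = numba.uint8(1)
        edge_set[e2] = numba.uint8(1)
        if a < d:
            ea[i] = a
            eb[i] = d
        else:
            ea[i] = d
            eb[i] = a
        if c < b:
            ea[j] = c
            eb[j] = b
        else:
            ea[j] = b
            eb[j] = c


def random_rewire(
    G: nx.Graph,
    seed: int | np.random.Generator | None = None,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
) -> nx.Graph:
    """Degree-preserving randomization by attempted double-edge swaps.

    ``swaps_per_edge * |E|`` swaps are attempted; proposals creating a
    self-loop or an existing edge are skipped (so a triangle, which admits no
    valid swap, is returned unchanged).  The node set is identical to ``G``'s.
    """
    if G.number_of_edges() < 2:
        raise ValueError("graph too small to rewire: needs at least 2 edges")
    rng = np.random.default_rng(seed)
    # integer-encode nodes (sorted order) so the hot loop hashes ints, not tuples
    nodes = sorted(G.nodes())
    index = {node: i for i, node in enumerate(nodes)}
    n = np.int64(len(nodes))
    ea = np.empty(G.number_of_edges(), dtype=np.int64)
    eb = np.empty(G.number_of_edges(), dtype=np.int64)
    for k, (u, v) in enumerate(G.edges()):
        i, j = index[u], index[v]
        ea[k], eb[k] = (i, j) if i < j else (j, i)
    m = len(ea)
    attempts = int(swaps_per_edge * m)
    idx = rng.integers(0, m, size=(attempts, 2))
    flip = rng.random(attempts) < 0.5
    _swap_kernel(ea, eb, n, idx, flip)
    H = nx.Graph()
    H.add_nodes_from(G.nodes())
    H.add_edges_from((nodes[a], nodes[b]) for a, b in zip(ea.tolist(), eb.tolist()))
    return H


def _mean_adjacency(G: nx.Graph, index: Mapping[str, int]) -> sparse.csr_matrix:
    """Row-stochastic neighbor-averaging operator (zero rows for degree 0)."""
    n = len(index)
    rows, cols, vals = [], [], []
    for node, i in index.items():
        neighbors = list(G[node])
        if not neighbors:
            continue
        w = 1.0 / len(neighbors)
        for nb in neighbors:
            rows.append(i)
            cols.append(index[nb])
            vals.append(w)
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def netzcore(
    G: nx.Graph,
    seeds: DiseaseProteinSet,
    R: int = 1_000,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    swaps_per_edge: float = DEFAULT_SWAPS_PER_EDGE,
    threshold: float = Z_THRESHOLD,
) -> PropagationResult:
    """Propagate seed scores and z-normalize against rewired networks."""
    if R < 2:
        raise ValueError("need at least 2 random networks to compute z-scores")
    nodes = sorted(G.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    present = seeds.proteins & set(nodes)
    absent = len(seeds.proteins) - len(present)
    if not present:
        raise ValueError(f"no seed proteins of {seeds.name!r} present in the network")
    if absent:
        logger.info("disease %r: %d seed(s) absent from the network", seeds.name, absent)

    s0 = np.zeros(len(nodes))
    s0[[index[p] for p in present]] = 1.0

    children = np.random.SeedSequence(seed).spawn(R)
    operators = [
        _mean_adjacency(
            random_rewire(G, np.random.default_rng(c), swaps_per_edge), index
        )
        for c in children
    ]
    P_real = _mean_adjacency(G, index)

    real = s0.copy()
    rand = np.tile(s0, (R, 1))
    degenerate = np.zeros(len(nodes), dtype=bool)
    for _ in range(iterations):
        raw_real = P_real @ real
        raw_rand = np.vstack([op @ rand[r] for r, op in enumerate(operators)])
        mu = raw_rand.mean(axis=0)
        sd = raw_rand.std(axis=0, ddof=1)
        # relative tolerance: an all-but-identical null (float noise) is
        # degenerate, not a license for astronomically large z-scores
        ok = sd > 1e-9 * np.maximum(1.0, np.abs(mu))
        inv = np.where(ok, 1.0 / np.where(ok, sd, 1.0), 0.0)
        # the same per-node standardization is applied to every network, so
        # real and random scores stay on one scale across iterations (the
        # random ensemble is z-scored against itself: mean 0, sd 1 per node)
        real = (raw_real - mu) * inv
        rand = (raw_rand - mu) * inv
        degenerate = ~ok

    return PropagationResult(
        disease_name=seeds.name,
        seed_nodes=frozenset(present),
        scores={n: float(real[index[n]]) for n in nodes},
        degenerate=frozenset(n for n in nodes if degenerate[index[n]]),
        iterations=iterations,
        R_networks=R,
        threshold=threshold,
    )


def candidate_table(
    results: Sequence[PropagationResult],
    known: Mapping[str, DiseaseProteinSet] | None = None,
    threshold: float = Z_THRESHOLD,
) -> pd.DataFrame:
    """Ranked candidate table across diseases.

    Per disease a protein shows ``"exp"`` when experimentally known, its
    z-score when strictly above ``threshold``, and blank otherwise.  Rows are
    ranked by the mean of the *shown* z-scores (known entries carry no z and
    are excluded from the mean); proteins with two or more non-blank entries
    are multimorbidity candidates.  Rows blank everywhere are dropped.
    """
    if not results:
        raise ValueError("no propagation results")
    if known is None:
        known = {r.disease_name: DiseaseProteinSet(r.disease_name, r.seed_nodes)
                 for r in results}
    universes = [set(r.scores) for r in results]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("propagation results cover different node universes")

    records = []
    for node in sorted(universes[0]):
        row: dict[str, object] = {"protein": node}
        shown_z: list[float] = []
        n_assoc = 0
        for r in results:
            col = r.disease_name
            if node in known[col].proteins:
                row[col] = "exp"
                n_assoc += 1
            elif r.scores[node] > threshold:
                z = r.scores[node]
                row[col] = z
                shown_z.append(z)
                n_assoc += 1
            else:
                row[col] = ""
        if n_assoc == 0:
            continue
        row["mean_z"] = float(np.mean(shown_z)) if shown_z else np.nan
        row["n_diseases"] = n_assoc
        row["multimorbid"] = n_assoc >= 2
        records.append(row)
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return df
    return (
        df.sort_values(["mean_z", "protein"], ascending=[False, True], na_position="last")
        .reset_index(drop=True)
    )
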