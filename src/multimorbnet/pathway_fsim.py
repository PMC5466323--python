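"""Edge-based Functional Similarity (FSim) of diseases within pathways.

A pathway's edge universe is the set of network edges whose *both* endpoints
belong to the pathway (this keeps hub-driven edges from dragging a pathway
across the whole network).  Within that universe, an edge is associated to a
disease when *at least one* endpoint is a disease protein.  FSim of a disease
pair (or triad) on pathway *p* is the Jaccard index of the per-disease edge
sets e^p_dis:

    FSim^p = |e^p_dis1 ∩ e^p_dis2| / |e^p_dis1 ∪ e^p_dis2|

Edges capture how similarly two diseases perturb the pathway's internal
wiring, not merely whether they touch the same proteins.  Only pathways with
more than 2 edges in the network are eligible for testing.  Significance uses
the same binned node-swap null as the connectivity analysis, a one-sided
upper-tail z-test, and Benjamini-Hochberg correction across the eligible
pathways within each disease combination.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .fin_connectivity import binned_swap_replicates
from .io_formats import DiseaseProteinSet, PathwayAnnotation

logger = logging.getLogger(__name__)

MIN_PATHWAY_EDGES = 2  # eligible means strictly more edges than this


@dataclass(frozen=True)
class FsimResult:
    pathway_name: str
    diseases: tuple[str, ...]
    fsim: float | None
    numerator_edges: int
    denominator_edges: int
    eligible: bool
    covered: bool = True        # False when no disease touches the pathway
    z: float | None = None
    p_raw: float | None = None
    p_empirical: float | None = None
    p_bh: float | None = None


def disease_pathway_edges(
    pathway: PathwayAnnotation, disease: DiseaseProteinSet
) -> frozenset[tuple[str, str]]:
    """Pathway edges with at least one endpoint associated to the disease."""
    proteins = disease.proteins
    return frozenset(
        e for e in pathway.intra_edges if e[0] in proteins or e[1] in proteins
    )


def is_eligible(pathway: PathwayAnnotation, min_edges: int = MIN_PATHWAY_EDGES) -> bool:
    return pathway.n_edges > min_edges


def count_eligible_pathways(
    pathways: Sequence[PathwayAnnotation], min_edges: int = MIN_PATHWAY_EDGES
) -> int:
    """Number of pathways with more than ``min_edges`` edges in the network."""
    return sum(1 for p in pathways if is_eligible(p, min_edges))


def fsim(
    pathway: PathwayAnnotation, *diseases: DiseaseProteinSet
) -> FsimResult:
    """FSim of two or three diseases on one pathway.

    Ineligible pathways (<= 2 edges) yield an explicit ineligible result.
    An eligible pathway untouched by every disease yields FSim 0 with
    ``covered=False``.
    """
    if len(diseases) not in (2, 3):
        raise ValueError("FSim is defined for 2 or 3 diseases")
    names = tuple(d.name for d in diseases)
    if not is_eligible(pathway):
        return FsimResult(pathway.name, names, None, 0, 0, eligible=False)
    edge_sets = [disease_pathway_edges(pathway, d) for d in diseases]
    inter = frozenset.intersection(*edge_sets)
    union = frozenset.union(*edge_sets)
    if not union:
        return FsimResult(pathway.name, names, 0.0, 0, 0, eligible=True, covered=False)
    return FsimResult(
        pathway.name, names, len(inter) / len(union), len(inter), len(union),
        eligible=True,
    )


def fsim_pair(
    pathway: PathwayAnnotation, a: DiseaseProteinSet, b: DiseaseProteinSet
) -> FsimResult:
    return fsim(pathway, a, b)


def fsim_triad(
    pathway: PathwayAnnotation,
    a: DiseaseProteinSet,
    b: DiseaseProteinSet,
    c: DiseaseProteinSet,
) -> FsimResult:
    return fsim(pathway, a, b, c)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(pvals) == 0:
        return np.array([])
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def disease_combinations(
    sets: Sequence[DiseaseProteinSet],
) -> list[tuple[DiseaseProteinSet, ...]]:
    """All pairs, plus the triad when three diseases are given."""
    combos: list[tuple[DiseaseProteinSet, ...]] = list(itertools.combinations(sets, 2))
    if len(sets) == 3:
        combos.append(tuple(sets))
    return combos


def fsim_significance(
    G: nx.Graph,
    pathways: Sequence[PathwayAnnotation],
    sets: Sequence[DiseaseProteinSet],
    R: int = 1_000,
    seed: int | None = None,
) -> list[FsimResult]:
    """Observed FSim with swap-null significance for every disease combination.

    For each combination (3 pairs and the triad for three diseases), the
    binned node-swap null is generated once and every eligible pathway's FSim
    is evaluated on each replicate; one-sided z-test p-values are BH-adjusted
    across the eligible pathways of that combination.  When the null is
    degenerate (sd = 0) for a pathway, the add-one empirical p substitutes the
    z-test p in the BH family.
    """
    eligible = [p for p in pathways if is_eligible(p)]
    if not eligible:
        logger.warning("no eligible pathways (more than %d edges)", MIN_PATHWAY_EDGES)
    results: list[FsimResult] = []
    for combo_index, combo in enumerate(disease_combinations(sets)):
        observed = [fsim(p, *combo) for p in eligible]
        # one replicate stream per combination, derived from the master seed
        combo_seed = None if seed is None else (seed + 7919 * (combo_index + 1)) % (2**31)
        null_matrix = np.empty((R, len(eligible)), dtype=float)
        for r, rand_sets in enumerate(
            binned_swap_replicates(G, combo, R=R, seed=combo_seed)
        ):
            for j, p in enumerate(eligible):
                null_matrix[r, j] = fsim(p, *rand_sets).fsim
        mu = null_matrix.mean(axis=0)
        sd = null_matrix.std(axis=0, ddof=1)
        combo_results: list[FsimResult] = []
        for j, res in enumerate(observed):
            ge = int(np.sum(null_matrix[:, j] >= res.fsim))
            p_emp = (1 + ge) / (R + 1)
            if sd[j] > 0:
                z = (res.fsim - mu[j]) / sd[j]
                p_raw = float(stats.norm.sf(z))
            else:
                z = None
                p_raw = p_emp
            combo_results.append(
                replace(res, z=z, p_raw=p_raw, p_empirical=p_emp)
            )
        adjusted = bh_adjust([r.p_raw for r in combo_results])
        combo_results = [
            replace(r, p_bh=float(a)) for r, a in zip(combo_results, adjusted)
        ]
        results.extend(combo_results)
    return results
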