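"""Synthetic study generator with planted multimorbidity structure.

The generator emulates the statistical structure the pipeline assumes about
real data: a sparse interactome with heavy-tailed degrees, three disease
protein sets with controlled pairwise/triple overlap, dense pathway subgraphs
partially covered by the disease sets, a catalogue of decoy disease sets with
subtype (parent/child) links, and a noisy literature list enriched for the
planted multimorbidity proteins.  Every draw is deterministic under the
config seed.

Defaults mirror the real study's conditions: a 9,847-node preferential
attachment interactome with mean degree ≈ 31, disease sizes 196/49/40 with
intersection cells 11 (first two only), 30 (first and third only), 0 (second
and third only) and 5 (all three).  Generating at that scale takes seconds;
tests and the acceptance run use explicitly smaller ``n_nodes`` (documented
in the methods note).

:func:`paper_tables_fixture` returns the three allergic-disease sets encoded
from the printed shared-protein matrix, padded with reserved-prefix
placeholders for the unlisted unique members.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .io_formats import (
    CatalogueEntry,
    DiseaseCatalogue,
    DiseaseProteinSet,
    PathwayAnnotation,
)

logger = logging.getLogger(__name__)

#: reserved prefix for placeholder identifiers (never a valid accession)
PLACEHOLDER_PREFIX = "pad:"

# Shared proteins from the printed association matrix of the allergic-disease
# study: 5 in all three diseases, 11 in asthma+eczema only, 30 in
# asthma+rhinitis only, none in eczema+rhinitis only.
TRIPLE_SHARED = (
    "P05112", "P35225", "Q01638", "Q13478", "Q969D9",
)
ASTHMA_ECZEMA_ONLY = (
    "O95760", "P01584", "P05113", "P13501", "P40425", "P51671",
    "P51677", "Q8IZI9", "Q99466", "Q9Y496", "Q9Y4H4",
)
ASTHMA_RHINITIS_ONLY = (
    "P01303", "P01906", "P01909", "P01912", "P01920", "P13760",
    "P13761", "P16109", "P20039", "P21731", "P24394", "P50135",
    "P84022", "Q13093", "Q15399", "Q30134", "Q30167", "Q5Y7A7",
    "Q8NI36", "Q95IE3", "Q96D42", "Q96QA5", "Q9GIY3", "Q9HBE5",
    "Q9HBL0", "Q9NQ38", "Q9TQE0", "Q9UIL8", "Q9UKT9", "Q9UKW4",
)
ECZEMA_RHINITIS_ONLY: tuple[str, ...] = ()

DISEASE_TOTALS = {"asthma": 196, "eczema": 49, "rhinitis": 40}


@dataclass(frozen=True)
class StudyConfig:
    """Parameters of one synthetic study.

    ``overlap_spec`` gives the four intersection cells (AB-only, AC-only,
    BC-only, ABC); each disease's unique-member count is its total size minus
    its cells, and must be non-negative.  ``module_cohesion`` is the
    probability that a pair of proteins within one disease module receives an
    extra interaction, planting connectivity for the topological-overlap
    analysis.  ``pathway_disease_coverage`` is the fraction of a
    disease-shifted pathway's members drawn from the disease modules (half of
    the pathways are shifted, the rest are background).  ``lit_enrichment``
    is the probability that a true multimorbidity protein enters the
    literature list.
    """

    n_nodes: int = 9_847
    graph_model: str = "preferential_attachment"  # or erdos_renyi, configuration
    model_params: dict = field(default_factory=lambda: {"m": 16})
    disease_names: tuple[str, str, str] = ("asthma", "eczema", "rhinitis")
    disease_sizes: tuple[int, int, int] = (196, 49, 40)
    overlap_spec: tuple[int, int, int, int] = (11, 30, 0, 5)
    module_cohesion: float = 0.3
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (5, 20)
    pathway_density: float = 0.6
    pathway_disease_coverage: float = 0.5
    n_decoy_diseases: int = 30
    decoy_size_range: tuple[int, int] = (10, 200)
    decoy_child_prob: float = 0.3
    lit_enrichment: float = 0.8
    seed: int = 0

    def unique_sizes(self) -> tuple[int, int, int]:
        ab, ac, bc, abc = self.overlap_spec
        sa, sb, sc = self.disease_sizes
        ua = sa - ab - ac - abc
        ub = sb - ab - bc - abc
        uc = sc - ac - bc - abc
        if min(ua, ub, uc) < 0:
            raise ValueError(
                f"overlap_spec {self.overlap_spec} inconsistent with "
                f"disease_sizes {self.disease_sizes}"
            )
        return ua, ub, uc

    def validate(self) -> None:
        self.unique_sizes()
        for name, value in [
            ("module_cohesion", self.module_cohesion),
            ("pathway_density", self.pathway_density),
            ("pathway_disease_coverage", self.pathway_disease_coverage),
            ("lit_enrichment", self.lit_enrichment),
        ]:
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        total = sum(self.disease_sizes)
        if total > self.n_nodes:
            raise ValueError("disease sets cannot exceed the number of nodes")


def paper_like_config(seed: int = 0, n_nodes: int = 9_847, **overrides) -> StudyConfig:
    """The study-condition preset (full scale unless ``n_nodes`` is lowered)."""
    m = max(2, round(n_nodes * 16 / 9_847))  # keep mean degree roughly scale-free
    cfg = StudyConfig(n_nodes=n_nodes, model_params={"m": m}, seed=seed)
    return replace(cfg, **overrides) if overrides else cfg


@dataclass(frozen=True)
class StudyBundle:
    config: StudyConfig
    network: nx.Graph
    disease_sets: tuple[DiseaseProteinSet, ...]
    pathways: tuple[PathwayAnnotation, ...]
    catalogue: DiseaseCatalogue
    literature: frozenset[str]
    truth: dict


def _make_graph(cfg: StudyConfig, rng: np.random.Generator) -> nx.Graph:
    gseed = int(rng.integers(2**31))
    n = cfg.n_nodes
    if cfg.graph_model == "erdos_renyi":
        p = cfg.model_params.get("p", 0.01)
        G = nx.fast_gnp_random_graph(n, p, seed=gseed)
    elif cfg.graph_model == "preferential_attachment":
        m = cfg.model_params.get("m", 16)
        G = nx.barabasi_albert_graph(n, m, seed=gseed)
    elif cfg.graph_model == "configuration":
        gamma = cfg.model_params.get("gamma", 2.5)
        local = np.random.default_rng(gseed)
        degs = np.clip(local.zipf(gamma, size=n), 1, n - 1)
        if degs.sum() % 2:
            degs[0] += 1
        M = nx.configuration_model(degs.tolist(), seed=gseed)
        G = nx.Graph(M)
        G.remove_edges_from(nx.selfloop_edges(G))
    else:
        raise ValueError(f"unknown graph model {cfg.graph_model!r}")
    width = len(str(n - 1))
    return nx.relabel_nodes(G, {i: f"prot{i:0{width}d}" for i in G.nodes()})


def generate_study(cfg: StudyConfig) -> StudyBundle:
    """Generate a full synthetic study bundle, deterministic per seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    G = _make_graph(cfg, rng)
    nodes = sorted(G.nodes())

    # --- disease sets realizing the overlap cells exactly -----------------
    ab, ac, bc, abc = cfg.overlap_spec
    ua, ub, uc = cfg.unique_sizes()
    n_needed = abc + ab + ac + bc + ua + ub + uc
    chosen = [nodes[i] for i in rng.choice(len(nodes), size=n_needed, replace=False)]
    it = iter(chosen)

    def take(k: int) -> frozenset[str]:
        return frozenset(itertools.islice(it, k))

    cell_abc, cell_ab, cell_ac, cell_bc = take(abc), take(ab), take(ac), take(bc)
    only_a, only_b, only_c = take(ua), take(ub), take(uc)
    na, nb, nc = cfg.disease_names
    sets = (
        DiseaseProteinSet(na, cell_abc | cell_ab | cell_ac | only_a),
        DiseaseProteinSet(nb, cell_abc | cell_ab | cell_bc | only_b),
        DiseaseProteinSet(nc, cell_abc | cell_ac | cell_bc | only_c),
    )

    # --- plant module cohesion: extra edges within each disease module ----
    for s in sets:
        members = sorted(s.proteins)
        for x, y in itertools.combinations(members, 2):
            if not G.has_edge(x, y) and rng.random() < cfg.module_cohesion:
                G.add_edge(x, y)

    # --- pathways: dense subgraphs of three classes -----------------------
    # "core" pathways are built around the multimorbidity core (nodes shared
    # by >= 2 diseases), emulating pathways co-perturbed by all diseases;
    # "shifted" pathways draw from the whole disease union (dominated by the
    # largest disease, hence mostly single-disease signal); "background"
    # pathways avoid the disease modules entirely and serve as nulls
    disease_union = sorted(frozenset.union(*[s.proteins for s in sets]))
    shared_pool = sorted(
        p for p in disease_union if sum(p in s.proteins for s in sets) >= 2
    )
    background = sorted(set(nodes) - set(disease_union))
    pathways: list[PathwayAnnotation] = []
    pathway_types: list[str] = []
    lo, hi = cfg.pathway_size_range
    for i in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        draw = rng.random()
        ptype = "core" if draw < 0.25 else ("shifted" if draw < 0.5 else "background")
        if ptype == "background":
            mem = set()
        else:
            pool = shared_pool if ptype == "core" else disease_union
            k_dis = min(len(pool), round(size * cfg.pathway_disease_coverage))
            mem = {
                pool[j] for j in rng.choice(len(pool), size=k_dis, replace=False)
            }
        rest = size - len(mem)
        if rest > 0:
            mem |= {
                background[j]
                for j in rng.choice(len(background), size=rest, replace=False)
            }
        members = frozenset(mem)
        for x, y in itertools.combinations(sorted(members), 2):
            if not G.has_edge(x, y) and rng.random() < cfg.pathway_density:
                G.add_edge(x, y)
        intra = frozenset(
            (min(x, y), max(x, y))
            for x, y in itertools.combinations(sorted(members), 2)
            if G.has_edge(x, y)
        )
        pathways.append(PathwayAnnotation(f"pathway{i:03d}", members, intra))
        pathway_types.append(ptype)

    # --- decoy disease catalogue with subtype links -----------------------
    entries: list[CatalogueEntry] = []
    dlo, dhi = cfg.decoy_size_range
    for i in range(cfg.n_decoy_diseases):
        name = f"decoy{i:03d}"
        if entries and rng.random() < cfg.decoy_child_prob:
            parent = entries[int(rng.integers(len(entries)))]
            pool = sorted(parent.disease.proteins)
            size = max(1, int(rng.integers(1, max(2, len(pool)))))
            proteins = frozenset(
                pool[j] for j in rng.choice(len(pool), size=min(size, len(pool)), replace=False)
            )
            entries.append(
                CatalogueEntry(
                    DiseaseProteinSet(name, proteins),
                    parents=frozenset({parent.disease.name}),
                )
            )
        else:
            size = int(rng.integers(dlo, min(dhi, len(nodes)) + 1))
            proteins = frozenset(
                nodes[j] for j in rng.choice(len(nodes), size=size, replace=False)
            )
            entries.append(CatalogueEntry(DiseaseProteinSet(name, proteins)))
    catalogue = DiseaseCatalogue(entries)

    # --- noisy literature list enriched for multimorbidity nodes ----------
    multimorbid = sorted(
        p
        for p in disease_union
        if sum(p in s.proteins for s in sets) >= 2
    )
    lit = {p for p in multimorbid if rng.random() < cfg.lit_enrichment}
    non_mm = sorted(set(nodes) - set(multimorbid))
    n_noise = len(multimorbid)
    lit |= {
        non_mm[j] for j in rng.choice(len(non_mm), size=min(n_noise, len(non_mm)), replace=False)
    }

    truth = {
        "cells": {
            "ABC": sorted(cell_abc),
            "AB_only": sorted(cell_ab),
            "AC_only": sorted(cell_ac),
            "BC_only": sorted(cell_bc),
        },
        "unique": {
            na: sorted(only_a),
            nb: sorted(only_b),
            nc: sorted(only_c),
        },
        "multimorbid": multimorbid,
        "pathway_types": {p.name: t for p, t in zip(pathways, pathway_types)},
    }
    return StudyBundle(
        config=cfg,
        network=G,
        disease_sets=sets,
        pathways=tuple(pathways),
        catalogue=catalogue,
        literature=frozenset(lit),
        truth=truth,
    )


def paper_tables_fixture() -> tuple[DiseaseProteinSet, DiseaseProteinSet, DiseaseProteinSet]:
    """The three allergic-disease protein sets from the printed tables.

    Shared members are the printed accessions; unique members (not listed in
    the shared-protein matrix) are padded with reserved-prefix placeholders so
    that the per-disease totals are 196/49/40 and every intersection cell
    matches the printed counts (16 asthma∩eczema, 35 asthma∩rhinitis,
    5 eczema∩rhinitis, 5 triple).  Note the printed per-disease *unique*
    counts (150/44/38) are arithmetically inconsistent with these totals for
    eczema and rhinitis; this fixture keeps the set algebra (150/33/5 unique
    placeholders) so that totals and intersections are exact.
    """
    shared = {
        "asthma": set(TRIPLE_SHARED) | set(ASTHMA_ECZEMA_ONLY) | set(ASTHMA_RHINITIS_ONLY),
        "eczema": set(TRIPLE_SHARED) | set(ASTHMA_ECZEMA_ONLY) | set(ECZEMA_RHINITIS_ONLY),
        "rhinitis": set(TRIPLE_SHARED) | set(ASTHMA_RHINITIS_ONLY) | set(ECZEMA_RHINITIS_ONLY),
    }
    out = []
    for disease, total in DISEASE_TOTALS.items():
        members = set(shared[disease])
        n_pad = total - len(members)
        members |= {
            f"{PLACEHOLDER_PREFIX}{disease}:{i:03d}" for i in range(n_pad)
        }
        out.append(DiseaseProteinSet(disease, frozenset(members)))
    return tuple(out)
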