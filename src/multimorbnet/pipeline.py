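"""End-to-end orchestration: overlap → connectivity → FSim → prediction →
literature association, from one validated config, with seed-stamped outputs.

Each stage writes a plain TSV into the output directory and contributes to a
JSON run manifest (inputs, seeds, counts, library versions).  Re-running the
same config reproduces identical outputs.  Any stage failure raises
:class:`StageError` naming the stage; outputs of completed stages remain on
disk.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io_formats, overlap_stats
from .fin_connectivity import (
    binned_swap_null,
    edge_disease_overlap,
    mean_to_common,
    mean_to_unique,
)
from .guilt_prediction import (
    Z_THRESHOLD,
    PropagationResult,
    candidate_table,
    netzcore,
)
from .io_formats import DiseaseProteinSet
from .literature_assoc import fisher_association
from .pathway_fsim import count_eligible_pathways, fsim_significance

logger = logging.getLogger(__name__)

_STAGES = ("overlap", "connectivity", "fsim", "predict", "literature")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    fin: str
    sets: str
    output_dir: str
    pathways: str | None = None
    catalogue: str | None = None
    literature: str | None = None
    literature_fdr_max: float | None = None
    seed: int = 17
    R: dict = field(default_factory=lambda: {
        "overlap": 1000, "connectivity": 1000, "fsim": 1000, "predict": 1000,
    })
    proteome_size: int = overlap_stats.PROTEOME_SIZE
    iterations: int = 5
    swaps_per_edge: float = 100.0
    z_threshold: float = Z_THRESHOLD
    stages: tuple[str, ...] = _STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("fin", "sets"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name in ("pathways", "catalogue", "literature"):
            p = getattr(self, name)
            if p is not None and not Path(p).is_file():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for stage in self.stages:
            if stage not in _STAGES:
                raise ValueError(f"unknown stage {stage!r}")
        if "fsim" in self.stages and self.pathways is None:
            raise StageError("pathway_fsim", FileNotFoundError("no pathway file configured"))
        if "literature" in self.stages and self.literature is None:
            raise StageError("literature_assoc", FileNotFoundError("no literature file configured"))
        if self.z_threshold <= 0 or any(r <= 0 for r in self.R.values()):
            raise ValueError("thresholds and replicate counts must be positive")

    def stage_seed(self, stage: str) -> int:
        # fixed offsets keep stages independent yet reproducible from one seed
        return (self.seed + 104_729 * (_STAGES.index(stage) + 1)) % (2**31)


def _combinations(sets: Sequence[DiseaseProteinSet]):
    combos = list(itertools.combinations(sets, 2))
    if len(sets) == 3:
        combos.append(tuple(sets))
    return combos


def _combo_name(combo) -> str:
    return "+".join(s.name for s in combo)


def run_overlap(cfg: RunConfig, sets, outdir: Path, catalogue=None) -> pd.DataFrame:
    rows = []
    R = cfg.R.get("overlap", 1000)
    for combo in _combinations(sets):
        ov = (overlap_stats.jaccard_pair(*combo) if len(combo) == 2
              else overlap_stats.jaccard_triad(*combo))
        null = overlap_stats.proteome_null(
            [len(s) for s in combo], proteome_size=cfg.proteome_size,
            R=R, seed=cfg.stage_seed("overlap"),
        )
        try:
            zt = overlap_stats.z_test(ov.jaccard, null)
            z, p_z = zt.z, zt.p
        except ValueError:  # degenerate null: the empirical test still applies
            z = p_z = None
        et = overlap_stats.empirical_test(ov.jaccard, null)
        row = {
            "combination": _combo_name(combo),
            "intersection": ov.intersection_size,
            "union": ov.union_size,
            "jaccard": ov.jaccard,
            "null_mean": float(np.mean(null.samples)),
            "z": z,
            "p_z": p_z,
            "p_empirical": et.p,
        }
        if catalogue is not None:
            cnull = overlap_stats.catalogue_null(
                catalogue, k=len(combo), R=R, seed=cfg.stage_seed("overlap"),
            )
            row["p_catalogue"] = overlap_stats.empirical_test(ov.jaccard, cnull).p
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "overlap_report.tsv", sep="\t", index=False)
    return df


def run_connectivity(cfg: RunConfig, G: nx.Graph, sets, outdir: Path) -> pd.DataFrame:
    rows = []
    R = cfg.R.get("connectivity", 1000)
    for combo in _combinations(sets):
        for mode, fn in (
            ("common", lambda g, ss: mean_to_common(g, ss)),
            ("unique", lambda g, ss: mean_to_unique(g, ss)),
        ):
            obs = fn(G, combo)
            row = {
                "combination": _combo_name(combo),
                "mode": mode,
                "n_pairs": len(obs.pair_values),
                "mean_to": obs.mean_to,
                "note": obs.note,
            }
            if obs.computable:
                def stat(g, ss, _fn=fn):
                    r = _fn(g, ss)
                    return r.mean_to if r.computable else 0.0

                null = binned_swap_null(G, combo, stat, R=R,
                                        seed=cfg.stage_seed("connectivity"))
                row["null_mean"] = float(np.mean(null.samples))
                sd = float(np.std(null.samples, ddof=1))
                if sd > 0:
                    zt = overlap_stats.z_test(obs.mean_to, null)
                    row["z"], row["p_z"] = zt.z, zt.p
                row["p_empirical"] = overlap_stats.empirical_test(obs.mean_to, null).p
            rows.append(row)
        edge = edge_disease_overlap(G, combo)
        rows.append({
            "combination": _combo_name(combo),
            "mode": "edges",
            "n_pairs": edge.union_edges,
            "mean_to": edge.jaccard,
            "note": "edge-set jaccard; counts="
                    + ",".join(f"{k}:{v}" for k, v in edge.edge_counts.items()),
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "connectivity_report.tsv", sep="\t", index=False)
    return df


def run_fsim(cfg: RunConfig, G: nx.Graph, pathways, sets, outdir: Path) -> pd.DataFrame:
    results = fsim_significance(G, pathways, sets, R=cfg.R.get("fsim", 1000),
                                seed=cfg.stage_seed("fsim"))
    rows = [{
        "pathway": r.pathway_name,
        "combination": "+".join(r.diseases),
        "fsim": round(r.fsim, 2) if r.fsim is not None else None,
        "z": r.z,
        "p_raw": r.p_raw,
        "p_empirical": r.p_empirical,
        "p_bh": r.p_bh,
        "covered": r.covered,
    } for r in results]
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "fsim_table.tsv", sep="\t", index=False)
    return df


def run_predict(cfg: RunConfig, G: nx.Graph, sets, outdir: Path):
    results = []
    for i, s in enumerate(sets):
        results.append(netzcore(
            G, s, R=cfg.R.get("predict", 1000), iterations=cfg.iterations,
            seed=cfg.stage_seed("predict") + i, swaps_per_edge=cfg.swaps_per_edge,
            threshold=cfg.z_threshold,
        ))
    known = {s.name: s for s in sets}
    table = candidate_table(results, known, threshold=cfg.z_threshold)
    table.to_csv(outdir / "candidates.tsv", sep="\t", index=False)
    return results, table


def multimorbidity_predictions(
    results: Sequence[PropagationResult],
    known: dict[str, DiseaseProteinSet],
    combo_names: Sequence[str],
    threshold: float = Z_THRESHOLD,
) -> tuple[frozenset[str], frozenset[str]]:
    """Predicted multimorbidity proteins and the background for one combination.

    A protein counts as predicted for the combination when, for *every*
    disease in it, the protein is either newly called (z above threshold) or
    already known — excluding proteins known for all of them, which are not
    predictions.  Background: all network nodes minus those all-known
    proteins.
    """
    by_name = {r.disease_name: r for r in results}
    universe = frozenset(results[0].scores)
    called = {
        name: frozenset(
            n for n, z in by_name[name].scores.items() if z > threshold
        ) | (known[name].proteins & universe)
        for name in combo_names
    }
    in_all = frozenset.intersection(*[called[n] for n in combo_names])
    known_all = frozenset.intersection(
        *[known[n].proteins & universe for n in combo_names]
    )
    return in_all - known_all, universe - known_all


def run_literature(cfg: RunConfig, results, sets, lit: frozenset[str],
                   outdir: Path) -> pd.DataFrame:
    known = {s.name: s for s in sets}
    rows = []
    for combo in _combinations(sets):
        names = [s.name for s in combo]
        predicted, background = multimorbidity_predictions(
            results, known, names, threshold=cfg.z_threshold,
        )
        res = fisher_association(predicted, lit, background)
        rows.append({
            "combination": "+".join(names),
            "n_predicted": len(predicted),
            "n_literature": len(frozenset(lit) & background),
            "odds_ratio": res.odds_ratio,
            "ci_low": res.ci95[0],
            "ci_high": res.ci95[1],
            "p": res.p,
            "background": res.background_size,
            "degenerate": res.degenerate,
        })
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "literature_report.tsv", sep="\t", index=False)
    return df


def run_all(cfg: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "multimorbnet",
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": {s: cfg.stage_seed(s) for s in cfg.stages},
        "R": dict(cfg.R),
        "inputs": {k: getattr(cfg, k) for k in
                   ("fin", "sets", "pathways", "catalogue", "literature")},
        "versions": {
            "numpy": np.__version__,
            "networkx": nx.__version__,
            "pandas": pd.__version__,
        },
        "stages_run": [],
    }

    def _stage(name, fn):
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with the stage name
            raise StageError(name, exc) from exc
        manifest["stages_run"].append(name)
        return out

    G = _stage("io_formats", lambda: io_formats.read_edge_list(cfg.fin))
    sets = _stage("io_formats", lambda: io_formats.read_disease_sets(cfg.sets))
    manifest["network"] = {"nodes": G.number_of_nodes(), "edges": G.number_of_edges()}
    manifest["diseases"] = {s.name: len(s) for s in sets}
    restricted = [s.restrict_to(G) for s in sets]
    manifest["diseases_in_fin"] = {s.name: len(s) for s in restricted}

    catalogue = None
    if cfg.catalogue:
        catalogue = _stage("io_formats", lambda: io_formats.read_catalogue(cfg.catalogue))

    if "overlap" in cfg.stages:
        _stage("overlap_stats", lambda: run_overlap(cfg, sets, outdir, catalogue))
    if "connectivity" in cfg.stages:
        _stage("fin_connectivity", lambda: run_connectivity(cfg, G, restricted, outdir))
    if "fsim" in cfg.stages:
        pathways = _stage("io_formats", lambda: io_formats.read_pathways(cfg.pathways, G))
        manifest["eligible_pathways"] = count_eligible_pathways(pathways)
        _stage("pathway_fsim", lambda: run_fsim(cfg, G, pathways, restricted, outdir))
    results = None
    if "predict" in cfg.stages:
        results, _ = _stage("guilt_prediction", lambda: run_predict(cfg, G, restricted, outdir))
    if "literature" in cfg.stages:
        if results is None:
            raise StageError("literature_assoc",
                             RuntimeError("literature stage requires the predict stage"))
        lit = _stage("io_formats", lambda: io_formats.read_genie_table(
            cfg.literature, fdr_max=cfg.literature_fdr_max))
        _stage("literature_assoc",
               lambda: run_literature(cfg, results, restricted, lit, outdir))

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
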