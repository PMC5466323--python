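"""Jaccard overlap of disease protein sets with two null models.

For diseases *dis1*, *dis2* (and optionally *dis3*) with protein sets
``N_dis1``, ``N_dis2``, ... the fraction of shared proteins is the classical
Jaccard index |N_dis1 ∩ N_dis2| / |N_dis1 ∪ N_dis2| (triple intersection over
triple union for a triad).  Significance is assessed against

* a *proteome randomization* null: each disease redrawn uniformly without
  replacement, at its original size, from a proteome of 14,754 proteins;
  tested with a one-sided upper-tail z-test; and
* a *catalogue resampling* null: random pairs/trios of diseases from an
  immune-disease catalogue, rejecting combinations in which one disease is a
  subtype (descendant) of another; tested against the empirical distribution
  because the null is strongly skewed.

Empirical p-values use the add-one estimator (r+1)/(R+1), so they are never
exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .io_formats import DiseaseCatalogue, DiseaseProteinSet

logger = logging.getLogger(__name__)

PROTEOME_SIZE = 14_754
DEFAULT_REPLICATES = 1_000


@dataclass(frozen=True)
class OverlapResult:
    diseases: tuple[str, ...]
    intersection_size: int
    union_size: int
    jaccard: float


@dataclass(frozen=True)
class NullDistribution:
    """Samples of a statistic under a stated randomization scheme."""

    statistic_name: str
    samples: np.ndarray
    method: str
    seed: int | None = None

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(samples)):
            raise ValueError("null distribution contains non-finite samples")
        object.__setattr__(self, "samples", samples)

    @property
    def R(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class TestResult:
    observed: float
    z: float | None
    p: float
    test: str  # "z_test" or "empirical"


def _overlap(sets: Sequence[DiseaseProteinSet]) -> OverlapResult:
    protein_sets = [s.proteins for s in sets]
    if all(len(p) == 0 for p in protein_sets):
        raise ValueError("Jaccard undefined: all protein sets are empty")
    if any(len(p) == 0 for p in protein_sets):
        logger.warning(
            "Jaccard of %s: at least one set is empty, overlap is 0",
            [s.name for s in sets],
        )
    inter = frozenset.intersection(*protein_sets)
    union = frozenset.union(*protein_sets)
    return OverlapResult(
        diseases=tuple(s.name for s in sets),
        intersection_size=len(inter),
        union_size=len(union),
        jaccard=len(inter) / len(union),
    )


def jaccard_pair(a: DiseaseProteinSet, b: DiseaseProteinSet) -> OverlapResult:
    """Jaccard index of two disease protein sets; symmetric in its arguments."""
    return _overlap([a, b])


def jaccard_triad(
    a: DiseaseProteinSet, b: DiseaseProteinSet, c: DiseaseProteinSet
) -> OverlapResult:
    """Triple-intersection-over-triple-union Jaccard for three diseases."""
    return _overlap([a, b, c])


def proteome_null(
    set_sizes: Sequence[int],
    proteome_size: int = PROTEOME_SIZE,
    R: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    statistic: str = "jaccard",
) -> NullDistribution:
    """Null distribution of the pair/triad overlap under proteome randomization.

    Each replicate draws one uniform sample without replacement per disease,
    at its original size, from a proteome of ``proteome_size`` proteins, and
    records the Jaccard index (or the raw intersection size when
    ``statistic="intersection"``).
    """
    sizes = [int(s) for s in set_sizes]
    if len(sizes) not in (2, 3):
        raise ValueError("set_sizes must have length 2 or 3")
    if any(s <= 0 for s in sizes):
        raise ValueError("set sizes must be positive")
    if any(s > proteome_size for s in sizes):
        raise ValueError("a disease set cannot exceed the proteome size")
    if statistic not in ("jaccard", "intersection"):
        raise ValueError(f"unknown statistic {statistic!r}")

    rng = np.random.default_rng(seed)
    samples = np.empty(R, dtype=float)
    for r in range(R):
        draws = [rng.permutation(proteome_size)[:s] for s in sizes]
        inter = draws[0]
        for d in draws[1:]:
            inter = np.intersect1d(inter, d, assume_unique=True)
        if statistic == "intersection":
            samples[r] = len(inter)
        else:
            union = draws[0]
            for d in draws[1:]:
                union = np.union1d(union, d)
            samples[r] = len(inter) / len(union)
    return NullDistribution(
        statistic_name=f"{statistic}_{len(sizes)}sets",
        samples=samples,
        method="proteome_randomization",
        seed=seed,
    )


def default_statistic(k: int) -> Callable[[Sequence[DiseaseProteinSet]], float]:
    """The k-set Jaccard index as a catalogue-null statistic."""

    def stat(sets: Sequence[DiseaseProteinSet]) -> float:
        return _overlap(list(sets)).jaccard

    return stat


def catalogue_null(
    catalogue: DiseaseCatalogue,
    k: int,
    R: int = DEFAULT_REPLICATES,
    seed: int | None = None,
    statistic: Callable[[Sequence[DiseaseProteinSet]], float] | None = None,
    max_consecutive_rejects: int = 10_000,
) -> NullDistribution:
    """Empirical null from random pairs/trios of catalogue diseases.

    Each replicate draws ``k`` distinct diseases, rejecting any draw in which
    one is an ancestor or descendant of another; combinations are drawn with
    replacement across replicates.  ``statistic`` receives the k drawn
    protein sets and defaults to their Jaccard index.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    names = catalogue.names
    if len(names) < k:
        raise ValueError(f"catalogue has fewer than {k} diseases")
    if statistic is None:
        statistic = default_statistic(k)

    rng = np.random.default_rng(seed)
    samples = np.empty(R, dtype=float)
    rejects = 0
    r = 0
    while r < R:
        idx = rng.choice(len(names), size=k, replace=False)
        chosen = [names[i] for i in idx]
        if any(
            catalogue.related(chosen[i], chosen[j])
            for i in range(k)
            for j in range(i + 1, k)
        ):
            rejects += 1
            if rejects >= max_consecutive_rejects:
                raise ValueError(
                    f"no valid {k}-subset of unrelated catalogue diseases found "
                    f"after {rejects} consecutive rejected draws"
                )
            continue
        rejects = 0
        samples[r] = statistic([catalogue.get(n) for n in chosen])
        r += 1
    return NullDistribution(
        statistic_name=f"catalogue_statistic_{k}sets",
        samples=samples,
        method="catalogue_resampling",
        seed=seed,
    )


def z_test(observed: float, null: NullDistribution) -> TestResult:
    """One-sided upper-tail z-test of ``observed`` against the null samples."""
    if null.R < 2:
        raise ValueError("z-test requires at least 2 null samples")
    mean = float(np.mean(null.samples))
    sd = float(np.std(null.samples, ddof=1))
    if sd == 0.0:
        raise ValueError(
            "null distribution is degenerate (sd = 0); use empirical_test"
        )
    z = (observed - mean) / sd
    p = float(stats.norm.sf(z))
    return TestResult(observed=float(observed), z=z, p=max(p, np.nextafter(0, 1)), test="z_test")


def empirical_test(observed: float, null: NullDistribution) -> TestResult:
    """Add-one empirical upper-tail p: (1 + #{samples >= observed}) / (R + 1)."""
    if null.R < 2:
        raise ValueError("empirical test requires at least 2 null samples")
    r = int(np.sum(null.samples >= observed))
    p = (1 + r) / (null.R + 1)
    return TestResult(observed=float(observed), z=None, p=p, test="empirical")
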