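"""Fisher's exact association between predicted candidates and a literature
gene list.

Predictions and the literature list are crossed over a background universe
(by default the network nodes minus the proteins already experimentally known
for the disease combination — the magnitude of the odds ratio depends on this
choice, so it is explicit and configurable).  The two-sided exact p-value and
the conditional maximum-likelihood odds ratio with its exact 95% confidence
interval are reported, alongside the sample (cross-product) odds ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float          # conditional MLE; inf/nan flagged via degenerate
    odds_ratio_sample: float   # cross-product ad/bc
    ci95: tuple[float, float]
    p: float
    background_size: int
    degenerate: bool = False   # zero margin: OR undefined, p forced to 1


def fisher_association(
    predicted: frozenset[str] | set[str],
    literature: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    ci: bool = True,
) -> ContingencyResult:
    """Cross predicted vs literature membership over ``background``.

    ``predicted`` must be a subset of the background; the literature list is
    intersected with it (text mining routinely returns genes outside the
    network universe).
    """
    background = frozenset(background)
    if not background:
        raise ValueError("empty background universe")
    predicted = frozenset(predicted)
    if not predicted <= background:
        raise ValueError(
            f"{len(predicted - background)} predicted protein(s) outside the background"
        )
    literature = frozenset(literature) & background

    a = len(predicted & literature)
    b = len(predicted - literature)
    c = len(literature - predicted)
    d = len(background) - a - b - c
    table = ((a, b), (c, d))

    # a zero margin (empty/full predicted or literature) carries no information
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return ContingencyResult(
            table=table,
            odds_ratio=float("nan"),
            odds_ratio_sample=float("nan"),
            ci95=(float("nan"), float("nan")),
            p=1.0,
            background_size=len(background),
            degenerate=True,
        )

    arr = np.array(table)
    p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
    res = _odds_ratio(arr, kind="conditional")
    if ci:
        interval = res.confidence_interval(confidence_level=0.95)
        ci95 = (float(interval.low), float(interval.high))
    else:
        ci95 = (float("nan"), float("nan"))
    sample_or = (a * d) / (b * c) if b * c > 0 else float("inf")
    return ContingencyResult(
        table=table,
        odds_ratio=float(res.statistic),
        odds_ratio_sample=sample_or,
        ci95=ci95,
        p=min(p, 1.0),
        background_size=len(background),
    )
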