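"""Pathway-enrichment and tandem-substitution statistics.

The contingency construction (variants vs callable base pairs by pathway
class) is explicit input rather than hard-coded, since the observation unit
behind published per-base tests varies; helpers build the table from a
candidate set plus panel.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import AmpliconPanel, InputError

logger = logging.getLogger(__name__)

#: relative tolerance when comparing table probabilities for the two-tailed sum
TIE_RTOL = 1e-7


@dataclass(frozen=True)
class EnrichmentInput:
    """Variant and callable-bp counts split by pathway class."""

    n_pathway_variants: int
    n_other_variants: int
    bp_pathway: int
    bp_other: int

    def __post_init__(self) -> None:
        if min(self.n_pathway_variants, self.n_other_variants) < 0:
            raise InputError("variant counts must be non-negative")
        if min(self.bp_pathway, self.bp_other) <= 0:
            raise InputError("callable bp totals must be positive")

    def table(self) -> list[list[int]]:
        return [
            [self.n_pathway_variants, self.bp_pathway - self.n_pathway_variants],
            [self.n_other_variants, self.bp_other - self.n_other_variants],
        ]


@dataclass(frozen=True)
class EnrichmentResult:
    fisher_p: float
    log_odds: float
    wald_p: float
    tandem_fold: float
    table: tuple[tuple[int, int], tuple[int, int]]


def fisher_exact_two_tailed(table: Sequence[Sequence[int]]) -> float:
    """Two-tailed Fisher's exact P by the sum-of-smaller-probabilities rule.

    Sums hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's (within
    ``TIE_RTOL`` relative, for ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise InputError("2x2 table cells must be non-negative")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + TIE_RTOL)].sum())
    return min(p, 1.0)


def per_base_logistic(inp: EnrichmentInput) -> tuple[float, float]:
    """Per-base logistic regression of variant presence on pathway class.

    With a single binary predictor the MLE coefficient is the closed-form
    log odds ratio of the 2x2 table; a zero cell gets the Haldane-Anscombe
    0.5 correction. Returns (coefficient, two-sided Wald P).
    """
    k1, n1 = inp.n_pathway_variants, inp.bp_pathway
    k0, n0 = inp.n_other_variants, inp.bp_other
    cells = [k1, n1 - k1, k0, n0 - k0]
    if min(cells) == 0:
        logger.warning(
            "per_base_logistic: zero cell — applying Haldane-Anscombe correction"
        )
        cells = [c + 0.5 for c in cells]
    a, b, c, d = cells
    coef = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = coef / se
    wald_p = float(2.0 * stats.norm.sf(abs(z)))
    return coef, wald_p


def tandem_enrichment(
    n_tandem: int, n_total: int, background_rate: float
) -> float:
    """Observed tandem fraction over the background tandem rate."""
    if n_total == 0:
        raise InputError("tandem enrichment undefined for an empty variant set")
    if not 0.0 < background_rate <= 1.0:
        raise InputError("background_rate must lie in (0, 1]")
    if n_tandem > n_total:
        raise InputError("n_tandem exceeds n_total")
    return (n_tandem / n_total) / background_rate


def enrichment_input_from_candidates(
    candidates: pd.DataFrame, panel: AmpliconPanel
) -> EnrichmentInput:
    """Split distinct candidates and callable bp by RAS_MAPK membership."""
    bp_path = panel.callable_union("RAS_MAPK")
    bp_other = panel.callable_union() - bp_path
    in_path = []
    for r in candidates.itertuples(index=False):
        amps = panel.amplicons_covering(r.chrom, int(r.pos))
        in_path.append(any(a.pathway == "RAS_MAPK" for a in amps))
    n_path = int(sum(in_path))
    return EnrichmentInput(
        n_pathway_variants=n_path,
        n_other_variants=len(candidates) - n_path,
        bp_pathway=bp_path,
        bp_other=bp_other,
    )


def enrichment_report(
    candidates: pd.DataFrame,
    panel: AmpliconPanel,
    tandem_background_rate: float = 0.003,
) -> Optional[EnrichmentResult]:
    """All three statistics over a candidate set; None if the set is empty."""
    if candidates.empty:
        return None
    inp = enrichment_input_from_candidates(candidates, panel)
    table = inp.table()
    fisher_p = fisher_exact_two_tailed(table)
    coef, wald_p = per_base_logistic(inp)
    n_tandem = int(candidates["is_tandem"].sum()) if "is_tandem" in candidates else 0
    fold = tandem_enrichment(n_tandem, len(candidates), tandem_background_rate)
    return EnrichmentResult(
        fisher_p=fisher_p,
        log_odds=coef,
        wald_p=wald_p,
        tandem_fold=fold,
        table=tuple(tuple(row) for row in table),
    )
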