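"""Differential local enrichment: primary vs. control Fisher exact tests.

For each sub-region where a motif is significantly locally enriched in
the primary sequence set, a two-sided Fisher exact test compares the
proportion of best matches falling inside the sub-region between the
primary and control sets (2x2 table: success/failure x primary/control).
Fisher p-values are adjusted for the same number of multiple tests as
the enrichment p-values, and the "Fisher E-value" multiplies the
adjusted p-value by the number of motifs in the compendium.

A motif with no significantly enriched sub-region in the primary set
carries no evidence of differential enrichment; its Fisher adjusted
p-value is reported at the ceiling 1 (Fisher E-value = number of
motifs).

The control-suitability protocol uses the Fisher E-value of the known
motif for the ChIP-ed factor, run in both directions, to decide which
of two paired datasets can serve as the control: a significant Fisher
E-value (< 0.05) in direction X-vs-Y means Y is unsafe as a control,
while an E-value at or above 1 means Y is safe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import hypergeom

from .local_enrichment import (
    EnrichmentResult,
    RegionCandidate,
    adjust_pvalue,
    motif_evalue,
)
from .scanner import ScanResult

log = logging.getLogger(__name__)

#: Relative slack when comparing hypergeometric probabilities for the
#: two-sided tail (tables tied with the observed one in floating point).
TIE_SLACK = 1e-7

SIGNIFICANT_EVALUE = 0.05  # suitability protocol: "significantly enriched"
SAFE_EVALUE = 1.0          # suitability protocol: "much larger than 1"


@dataclass(frozen=True)
class Table2x2:
    """success/failure (rows) x primary/control (columns) counts."""

    a: int  # primary successes (best matches inside the region)
    b: int  # primary failures (outside)
    c: int  # control successes
    d: int  # control failures

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("table counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class DifferentialResult:
    """Fisher differential enrichment of one motif in one sub-region."""

    motif_id: str
    region: Optional[RegionCandidate]
    table: Optional[Table2x2]
    fisher_p_raw: float
    fisher_p_adj: float
    fisher_evalue: float
    odds_ratio: float


def build_table(
    primary: ScanResult, control: ScanResult, region: RegionCandidate
) -> Table2x2:
    """Count primary/control best matches inside vs. outside the region."""
    if primary.N != control.N:
        raise ValueError(
            f"primary N={primary.N} != control N={control.N}; "
            "sets must share sequence length and motif"
        )
    from .local_enrichment import count_in_region

    a = count_in_region(primary, region)
    c = count_in_region(control, region)
    return Table2x2(a, primary.S - a, c, control.S - c)


def fisher_two_sided(t: Table2x2) -> float:
    """Two-sided Fisher exact p-value.

    Sums the hypergeometric probabilities of all tables with the same
    margins whose probability is at most that of the observed table
    (within a small relative slack for floating-point ties).  An
    all-zero table has p = 1 by convention.
    """
    n1 = t.a + t.b          # primary total
    n2 = t.c + t.d          # control total
    k = t.a + t.c           # total successes
    total = t.total
    if total == 0:
        return 1.0
    lo = max(0, k - n2)
    hi = min(k, n1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, total, k, n1)
    observed = pmf[t.a - lo]
    p = float(pmf[pmf <= observed * (1.0 + TIE_SLACK)].sum())
    return min(p, 1.0)


def odds_ratio(t: Table2x2) -> float:
    """Effect size (a*d)/(b*c); Haldane-Anscombe +0.5 when any cell is 0."""
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def differential_analyze(
    primary: ScanResult,
    control: ScanResult,
    enriched: Sequence[EnrichmentResult],
    n_motifs: int = 1,
    n_tests: int | None = None,
) -> list[DifferentialResult]:
    """Fisher differential test on each primary-enriched sub-region.

    `enriched` must come from the primary set.  The Fisher adjustment
    reuses the enrichment multiple-test count n (taken from the
    enrichment results unless overridden).
    """
    results = []
    for enr in enriched:
        n = n_tests if n_tests is not None else enr.n_tests
        table = build_table(primary, control, enr.region)
        p_raw = fisher_two_sided(table)
        p_adj = adjust_pvalue(p_raw, n)
        results.append(
            DifferentialResult(
                motif_id=enr.motif_id,
                region=enr.region,
                table=table,
                fisher_p_raw=p_raw,
                fisher_p_adj=float(p_adj),
                fisher_evalue=motif_evalue(float(p_adj), n_motifs),
                odds_ratio=odds_ratio(table),
            )
        )
    return results


def ceiling_result(motif_id: str, n_motifs: int) -> DifferentialResult:
    """The no-evidence result: adjusted Fisher p at its ceiling of 1."""
    return DifferentialResult(
        motif_id=motif_id,
        region=None,
        table=None,
        fisher_p_raw=1.0,
        fisher_p_adj=1.0,
        fisher_evalue=float(n_motifs),
        odds_ratio=float("nan"),
    )


def best_differential(
    results: Sequence[DifferentialResult], motif_id: str, n_motifs: int
) -> DifferentialResult:
    """Most significant differential result, or the ceiling when empty."""
    if not results:
        return ceiling_result(motif_id, n_motifs)
    return min(results, key=lambda r: r.fisher_evalue)


@dataclass(frozen=True)
class SuitabilityVerdict:
    """Which of two paired datasets may serve as the control set.

    ``b_as_control`` is judged from the A-vs-B direction (primary=A,
    control=B) and ``a_as_control`` from B-vs-A.  Each is "safe"
    (Fisher E-value >= 1), "unsafe" (< 0.05) or "inconclusive".
    """

    b_as_control: str
    a_as_control: str
    verdict: str


def _judge(evalue: float) -> str:
    if evalue < SIGNIFICANT_EVALUE:
        return "unsafe"
    if evalue >= SAFE_EVALUE:
        return "safe"
    return "inconclusive"


def control_suitability(
    result_a_vs_b: DifferentialResult | float,
    result_b_vs_a: DifferentialResult | float,
) -> SuitabilityVerdict:
    """Apply the control-suitability protocol to both run directions.

    A significant Fisher E-value for the known motif in direction X-vs-Y
    shows the motif is relatively enriched in X, so Y missed true sites
    and is unsafe as a control; an E-value at or above 1 clears Y.
    """
    ev_ab = getattr(result_a_vs_b, "fisher_evalue", result_a_vs_b)
    ev_ba = getattr(result_b_vs_a, "fisher_evalue", result_b_vs_a)
    b_ok = _judge(float(ev_ab))
    a_ok = _judge(float(ev_ba))
    if a_ok == "safe" and b_ok == "safe":
        verdict = "both_safe"
    elif a_ok == "safe" and b_ok != "safe":
        verdict = "A_safe_as_control"
    elif b_ok == "safe" and a_ok != "safe":
        verdict = "B_safe_as_control"
    elif a_ok == "unsafe" and b_ok == "unsafe":
        verdict = "neither"
    else:
        verdict = "inconclusive"
    return SuitabilityVerdict(b_as_control=b_ok, a_as_control=a_ok, verdict=verdict)
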