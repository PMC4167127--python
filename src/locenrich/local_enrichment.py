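"""Local enrichment of best motif matches in sub-regions.

Model: if best sites were placed uniformly at random, a site would fall
in a sub-region covering M of the sequence's N possible start positions
with probability r = M/N.  With s of the S observed best sites inside
the sub-region, the enrichment p-value is the binomial upper tail
P(X >= s), X ~ Bin(S, r).  Raw p-values are adjusted for the n
sub-regions tested under an independence assumption,
p = 1 - (1 - p')^n, and the E-value multiplies the adjusted p-value by
the number of motifs in the input compendium.

Two search modes are supported: "central" tests only sub-regions
symmetric about the sequence center (one per admissible width, linear
in sequence length) and "local" tests sub-regions of every width and
placement on a configurable grid (quadratic).  Overlapping significant
sub-regions are reduced to a non-redundant set by a greedy sweep in
order of increasing raw p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binom

from .scanner import ScanResult

log = logging.getLogger(__name__)

#: Default width grid for local mode: bounds the quadratic enumeration
#: while covering the space; full enumeration available via parameters.
LOCAL_MIN_WIDTH = 10
LOCAL_WIDTH_STEP = 5

#: Default E-value gate for reporting regions (report-many, filter-later).
DEFAULT_ALPHA_EVALUE = 10.0


@dataclass(frozen=True)
class RegionCandidate:
    """A candidate sub-region: M start positions beginning at `start`.

    Spans the half-open start-index interval [start, start + M).
    """

    start: int
    M: int

    @property
    def end(self) -> int:
        return self.start + self.M

    def overlaps(self, other: "RegionCandidate") -> bool:
        return self.start < other.end and other.start < self.end

    def center_offset(self, N: int) -> float:
        """Region center in start-index units relative to the sequence center."""
        return self.start + (self.M - 1) / 2.0 - (N - 1) / 2.0


@dataclass
class EnrichmentResult:
    """Binomial enrichment of one motif in one sub-region.

    ``log_p_adj`` is the natural log of the adjusted p-value kept in
    log space so extremely significant motifs do not underflow to 0.
    """

    motif_id: str
    region: RegionCandidate
    r: float
    s: int
    S: int
    p_raw: float
    n_tests: int
    p_adj: float
    evalue: float
    log_p_adj: float = 0.0


def success_probability(M: int, N: int) -> float:
    """Probability r = M/N that a uniform best site starts in the region."""
    if M < 1 or M > N:
        raise ValueError(f"need 1 <= M <= N, got M={M}, N={N}")
    return M / N


def binomial_pvalue(s: int, S: int, r: float) -> float:
    """Upper-tail binomial probability P(X >= s), X ~ Bin(S, r)."""
    if not 0 <= s <= S:
        raise ValueError(f"need 0 <= s <= S, got s={s}, S={S}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"need 0 <= r <= 1, got r={r}")
    if s == 0:
        return 1.0
    return float(binom.sf(s - 1, S, r))


def adjust_pvalue(p_raw, n: int):
    """Multiple-test adjustment p = 1 - (1 - p')^n, computed stably.

    Accepts scalars or arrays; n >= 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    p = np.asarray(p_raw, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p_raw must be in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        adj = -np.expm1(n * np.log1p(-p))
    adj = np.where(p >= 1.0, 1.0, adj)
    adj = np.clip(adj, 0.0, 1.0)
    return float(adj) if np.isscalar(p_raw) else adj


def motif_evalue(p_adj: float, n_motifs: int) -> float:
    """E-value: expected number of motifs reaching this adjusted p-value."""
    if n_motifs < 1:
        raise ValueError("n_motifs must be >= 1")
    return p_adj * n_motifs


def log_adjusted_pvalue(log_p_raw: float, n: int) -> float:
    """Natural log of the adjusted p-value, stable for tiny raw p.

    For p' small enough that 1 - (1 - p')^n ~= n p', the log is
    computed as ln(n) + ln(p') so significance is preserved even when
    the adjusted p-value itself underflows.
    """
    p = float(np.exp(log_p_raw))
    if p > 1e-9:
        adj = adjust_pvalue(p, n)
        return float(np.log(adj)) if adj > 0 else float(np.log(n) + log_p_raw)
    return float(np.log(n) + log_p_raw)


def width_grid(
    N: int,
    mode: str,
    min_width: int | None = None,
    max_width: int | None = None,
    width_step: int | None = None,
) -> range:
    """Resolve the width grid for a search mode.

    Local mode defaults to widths LOCAL_MIN_WIDTH..N step LOCAL_WIDTH_STEP;
    central mode defaults to every width 1..N (the parity filter keeps
    only widths matching N's parity).
    """
    if mode not in ("central", "local"):
        raise ValueError("mode must be 'central' or 'local'")
    if min_width is None:
        min_width = LOCAL_MIN_WIDTH if mode == "local" else 1
    if max_width is None:
        max_width = N
    if width_step is None:
        width_step = LOCAL_WIDTH_STEP if mode == "local" else 1
    min_width = min(min_width, N)  # small-N fixtures: clamp rather than fail
    max_width = min(max_width, N)
    if min_width < 1 or min_width > max_width:
        raise ValueError(
            f"invalid width grid [{min_width}, {max_width}] step {width_step}"
        )
    return range(min_width, max_width + 1, width_step)


def enumerate_regions(
    N: int,
    mode: str = "local",
    min_width: int | None = None,
    max_width: int | None = None,
    width_step: int | None = None,
) -> list[RegionCandidate]:
    """All candidate sub-regions for the given mode and width grid.

    Local mode: every feasible start for every width on the grid.
    Central mode: only regions exactly centered in the N start
    positions, i.e. widths with the same parity as N, start = (N-M)/2.
    The length of the returned list is the multiple-test contribution.
    """
    grid = width_grid(N, mode, min_width, max_width, width_step)
    regions: list[RegionCandidate] = []
    if mode == "central":
        for M in grid:
            if (N - M) % 2 == 0:
                regions.append(RegionCandidate((N - M) // 2, M))
    else:
        for M in grid:
            for start in range(N - M + 1):
                regions.append(RegionCandidate(start, M))
    if not regions:
        raise ValueError("empty region grid")
    return regions


def count_in_region(sites: ScanResult, region: RegionCandidate) -> int:
    """Number of best sites starting inside the region."""
    if region.start < 0 or region.end > sites.N:
        raise ValueError("region out of range for this scan")
    return sum(region.start <= s.start < region.end for s in sites.sites)


def group_regions(regions: Sequence[RegionCandidate]) -> dict[int, np.ndarray]:
    """Group region starts by width M for vectorised p-value evaluation."""
    grouped: dict[int, list[int]] = {}
    for reg in regions:
        grouped.setdefault(reg.M, []).append(reg.start)
    return {M: np.asarray(starts, dtype=np.int64) for M, starts in grouped.items()}


def _sf_table(S: int, r: float) -> np.ndarray:
    """Lookup table t[k] = P(X >= k) for X ~ Bin(S, r), k = 0..S."""
    tbl = binom.sf(np.arange(S + 1) - 1, S, r)
    tbl[0] = 1.0
    return tbl


def raw_pvalues(counts: np.ndarray, S: int, regions: Sequence[RegionCandidate]) -> np.ndarray:
    """Raw binomial p-values of all regions from a start-position histogram."""
    counts = np.asarray(counts)
    N = counts.size
    cs = np.concatenate([[0], np.cumsum(counts)])
    Ms = np.fromiter((reg.M for reg in regions), dtype=np.int64, count=len(regions))
    starts = np.fromiter((reg.start for reg in regions), dtype=np.int64, count=len(regions))
    p = np.empty(len(regions), dtype=float)
    for M in np.unique(Ms):
        mask = Ms == M
        s = cs[starts[mask] + M] - cs[starts[mask]]
        p[mask] = _sf_table(S, M / N)[s]
    return p


def min_raw_pvalue(
    counts2d: np.ndarray, S: int, grouped: dict[int, np.ndarray]
) -> np.ndarray:
    """Row-wise minimum raw p-value over a region grid.

    `counts2d` is a (B, N) matrix of start-position histograms, one row
    per independent scan (e.g. simulated motifs); all rows share S.
    Batched so that calibration over many simulated motifs stays cheap.
    """
    counts2d = np.atleast_2d(np.asarray(counts2d))
    B, N = counts2d.shape
    cs = np.concatenate([np.zeros((B, 1), dtype=np.int64),
                         np.cumsum(counts2d, axis=1)], axis=1)
    best = np.ones(B, dtype=float)
    for M, starts in grouped.items():
        s = cs[:, starts + M] - cs[:, starts]
        tbl = _sf_table(S, M / N)
        np.minimum(best, tbl[s].min(axis=1), out=best)
    return best


def _logsf_table(S: int, r: float) -> np.ndarray:
    """Lookup table t[k] = ln P(X >= k) for X ~ Bin(S, r), k = 0..S."""
    with np.errstate(divide="ignore"):
        tbl = binom.logsf(np.arange(S + 1) - 1, S, r)
    tbl[0] = 0.0
    return tbl


def score_regions(
    scan: ScanResult,
    regions: Sequence[RegionCandidate],
    n_tests: int,
    n_motifs: int = 1,
) -> list[EnrichmentResult]:
    """Binomial test of every candidate region for one scanned motif."""
    counts = scan.start_counts()
    p_raw = raw_pvalues(counts, scan.S, regions)
    p_adj = adjust_pvalue(p_raw, n_tests)
    # log-space raw p-values, for reporting very significant motifs
    cs = np.concatenate([[0], np.cumsum(counts)])
    Ms = np.fromiter((reg.M for reg in regions), dtype=np.int64, count=len(regions))
    starts = np.fromiter(
        (reg.start for reg in regions), dtype=np.int64, count=len(regions)
    )
    log_p_raw = np.empty(len(regions), dtype=float)
    for M in np.unique(Ms):
        mask = Ms == M
        s = cs[starts[mask] + M] - cs[starts[mask]]
        log_p_raw[mask] = _logsf_table(scan.S, M / scan.N)[s]
    results = []
    for reg, pr, pa, lpr in zip(regions, p_raw, p_adj, log_p_raw):
        s = int(cs[reg.end] - cs[reg.start])
        results.append(
            EnrichmentResult(
                motif_id=scan.motif_id,
                region=reg,
                r=reg.M / scan.N,
                s=s,
                S=scan.S,
                p_raw=float(pr),
                n_tests=n_tests,
                p_adj=float(pa),
                evalue=motif_evalue(float(pa), n_motifs),
                log_p_adj=log_adjusted_pvalue(float(lpr), n_tests),
            )
        )
    return results


def _rank_key(res: EnrichmentResult):
    # ties in p_raw: smaller M, then smaller start (deterministic output)
    return (res.p_raw, res.region.M, res.region.start)


def select_nonoverlapping(
    results: Iterable[EnrichmentResult],
    alpha_evalue: float = DEFAULT_ALPHA_EVALUE,
) -> list[EnrichmentResult]:
    """Greedy non-redundant selection of significant sub-regions.

    Results with E-value <= `alpha_evalue` are sorted by increasing raw
    p-value and emitted in turn unless they overlap an already-emitted
    region.
    """
    significant = sorted(
        (res for res in results if res.evalue <= alpha_evalue), key=_rank_key
    )
    chosen: list[EnrichmentResult] = []
    for res in significant:
        if not any(res.region.overlaps(c.region) for c in chosen):
            chosen.append(res)
    return chosen


def analyze_motif(
    scan: ScanResult,
    mode: str = "local",
    min_width: int | None = None,
    max_width: int | None = None,
    width_step: int | None = None,
    n_motifs: int = 1,
    n_threshold_tests: int = 1,
    alpha_evalue: float = DEFAULT_ALPHA_EVALUE,
    keep_best: bool = False,
) -> list[EnrichmentResult]:
    """Full local-enrichment analysis of one scanned motif.

    Enumerates candidate regions, tests each, adjusts with
    n = (#regions) x (#thresholds tried), and greedily selects
    non-overlapping significant regions.  Central mode reports the
    single most significant centered region.  With ``keep_best`` the
    best region is returned even when nothing passes the E-value gate
    (so compendium-wide rankings are total).
    """
    if scan.S == 0:
        log.info("motif %s: no best matches above threshold; skipped", scan.motif_id)
        return []
    regions = enumerate_regions(scan.N, mode, min_width, max_width, width_step)
    n_tests = len(regions) * max(1, n_threshold_tests)
    results = score_regions(scan, regions, n_tests, n_motifs)
    selected = select_nonoverlapping(results, alpha_evalue)
    if mode == "central":
        selected = selected[:1]
    if keep_best and not selected:
        selected = [min(results, key=_rank_key)]
    return selected
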