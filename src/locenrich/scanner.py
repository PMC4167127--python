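"""Best-match PWM scanning.

Each sequence contributes at most one site: the highest-scoring
placement of the motif over all start positions (and both strands for
DNA).  A '-' strand site is indexed by its leftmost forward-strand
base, so the trial space of start positions is the same N = L - w + 1
regardless of strand mode.  Score ties are broken uniformly at random
from a caller-seeded stream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .motif_model import (
    DNA,
    Background,
    Motif,
    NEG_SENTINEL,
    ScoringMatrix,
    reverse_complement_matrix,
    to_log_odds,
)
from .sequence_io import SequenceSet

log = logging.getLogger(__name__)

#: Default fixed score threshold in bits.
DEFAULT_THRESHOLD = 5.0

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@dataclass(frozen=True)
class BestSite:
    """The single best motif match in one sequence."""

    seq_index: int
    start: int          # 0-based leftmost forward-strand base
    strand: str         # '+' or '-'
    score: float        # bits


@dataclass
class ScanResult:
    """Best sites for one motif over a sequence set.

    ``S`` is the number of sequences with a qualifying site and ``N``
    the number of possible motif start positions per sequence.
    """

    motif_id: str
    threshold: float
    sites: list[BestSite]
    N: int
    n_sequences: int

    @property
    def S(self) -> int:
        return len(self.sites)

    def start_counts(self) -> np.ndarray:
        """Histogram of site starts over the N start positions."""
        counts = np.zeros(self.N, dtype=np.int64)
        for site in self.sites:
            counts[site.start] += 1
        return counts


def encode(seq: str) -> np.ndarray:
    """Encode a sequence as int8 codes (A=0 C=1 G=2 T/U=3 N=4)."""
    return np.array([_CODE[ch] for ch in seq], dtype=np.int8)


def _position_scores(codes: np.ndarray, sm: ScoringMatrix) -> np.ndarray:
    """Scores of every start position of `sm` along encoded sequence `codes`."""
    w = sm.width
    npos = codes.size - w + 1
    # 5-letter lookup: N scores the negative sentinel at every column
    lut = np.hstack([sm.scores, np.full((w, 1), NEG_SENTINEL)])
    total = np.zeros(npos, dtype=float)
    for j in range(w):
        total += lut[j, codes[j : j + npos]]
    return total


def best_site(
    seq: str,
    sm: ScoringMatrix,
    strands: str = "both",
    threshold: float = DEFAULT_THRESHOLD,
    rng: Optional[np.random.Generator] = None,
    seq_index: int = 0,
) -> Optional[BestSite]:
    """Best-scoring placement of the motif in one sequence, or None.

    With ``strands="both"`` the reverse-complement matrix is scored at
    the same forward start positions.  Exact score ties (across both
    positions and strands) are broken uniformly at random via `rng`.
    """
    if strands not in ("single", "both"):
        raise ValueError("strands must be 'single' or 'both'")
    codes = encode(seq) if isinstance(seq, str) else seq
    if codes.size < sm.width:
        raise ValueError(
            f"sequence length {codes.size} < motif width {sm.width}"
        )
    fwd = _position_scores(codes, sm)
    if strands == "both":
        if sm.alphabet != DNA:
            raise ValueError("double-stranded scanning requires DNA")
        rev = _position_scores(codes, reverse_complement_matrix(sm))
        all_scores = np.stack([fwd, rev])      # (2, npos)
    else:
        all_scores = fwd[None, :]
    best = all_scores.max()
    # a placement overlapping an N (or a zero-probability letter with
    # pseudo=0) scores at or below the sentinel: never a match
    if best <= NEG_SENTINEL / 2 or not (best >= threshold):
        return None
    tied = np.argwhere(all_scores == best)
    if len(tied) == 1:
        row, col = tied[0]
    else:
        if rng is None:
            rng = np.random.default_rng(0)
        row, col = tied[rng.integers(len(tied))]
    strand = "+" if row == 0 else "-"
    return BestSite(seq_index, int(col), strand, float(best))


def scan_set(
    seqs: SequenceSet,
    motif: Motif,
    bg: Background,
    strands: str = "both",
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
    pseudo: float = 0.1,
) -> ScanResult:
    """Scan every sequence for its best match above `threshold`.

    Sequences with no placement reaching the threshold contribute
    nothing to S.
    """
    if seqs.length < motif.width:
        raise ValueError(
            f"sequence length {seqs.length} < motif width {motif.width}"
        )
    sm = to_log_odds(motif, bg, pseudo)
    sites = []
    for idx, (rid, seq) in enumerate(seqs.records):
        # per-sequence tie-break stream keyed by the record id, so the
        # scan is equivariant under permutation of the input records
        rng = np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(rid.encode())])
        site = best_site(seq, sm, strands, threshold, rng, seq_index=idx)
        if site is not None:
            sites.append(site)
    N = seqs.length - motif.width + 1
    return ScanResult(motif.id, threshold, sites, N, len(seqs))


class ThresholdResult(NamedTuple):
    threshold: float
    scan: "ScanResult"
    n_thresholds_tested: int


def optimize_threshold(
    seqs_primary: SequenceSet,
    motif: Motif,
    bg: Background,
    strands: str = "both",
    seed: int = 0,
    mode: str = "central",
    min_width: int | None = None,
    max_width: int | None = None,
    width_step: int | None = None,
    max_candidates: int = 100,
    pseudo: float = 0.1,
) -> Optional[ThresholdResult]:
    """Pick the score threshold minimising the motif's adjusted p-value.

    Candidate thresholds are the distinct best-match scores observed in
    the primary set with no threshold (quantile-thinned to at most
    `max_candidates`).  Raising the threshold to a candidate simply
    drops best sites scoring below it, so candidates are evaluated by
    filtering the unthresholded scan.  The multiple-test count n is
    multiplied by the number of candidates evaluated, a conservative
    account of the extra optimisation.  Returns None when no sequence
    has any match at all.
    """
    from . import local_enrichment as le  # deferred: avoids import cycle

    base = scan_set(seqs_primary, motif, bg, strands, -np.inf, seed, pseudo)
    if base.S == 0:
        return None
    scores = np.array([s.score for s in base.sites])
    candidates = np.unique(scores)
    if candidates.size > max_candidates:
        qs = np.linspace(0, 1, max_candidates)
        candidates = np.unique(np.quantile(candidates, qs, method="nearest"))
    n_cand = int(candidates.size)
    regions = le.enumerate_regions(
        base.N, mode, min_width, max_width, width_step
    )
    grouped = le.group_regions(regions)
    n_tests = len(regions) * n_cand
    best_padj = np.inf
    best_thr = None
    for thr in candidates:  # ascending: ties resolve to the lower threshold
        kept = scores >= thr
        S = int(kept.sum())
        if S == 0:
            continue
        counts = np.zeros(base.N, dtype=np.int64)
        for site, keep in zip(base.sites, kept):
            if keep:
                counts[site.start] += 1
        p_raw_min = le.min_raw_pvalue(counts[None, :], S, grouped)[0]
        padj = le.adjust_pvalue(p_raw_min, n_tests)
        if padj < best_padj:
            best_padj = padj
            best_thr = float(thr)
    if best_thr is None:
        return None
    kept_sites = [s for s in base.sites if s.score >= best_thr]
    scan = ScanResult(motif.id, best_thr, kept_sites, base.N, base.n_sequences)
    return ThresholdResult(best_thr, scan, n_cand)
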