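"""Motif models: MEME-format parsing and log-odds scoring matrices.

A motif is a position probability matrix (PPM) over the DNA or RNA
alphabet.  For scanning, the PPM is converted to a log-odds scoring
matrix in bits against a 0-order background, with a proportional
pseudocount so that zero probabilities do not produce infinite scores
unless explicitly requested (pseudo=0), in which case a large negative
sentinel keeps arithmetic finite.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

log = logging.getLogger(__name__)

DNA = "ACGT"
RNA = "ACGU"

#: Sentinel replacing -inf log-odds scores so that window sums stay finite.
NEG_SENTINEL = -1e30

_COMPLEMENT_ORDER = np.array([3, 2, 1, 0])  # A<->T, C<->G


@dataclass(frozen=True, eq=False)
class Motif:
    """A position probability matrix over ACGT (or ACGU).

    Parameters
    ----------
    id:
        Motif identifier (first token after ``MOTIF`` in MEME format).
    name:
        Alternate/human-readable name; may equal ``id``.
    alphabet:
        ``"ACGT"`` for DNA, ``"ACGU"`` for RNA.
    probs:
        ``(width, 4)`` matrix; every row sums to 1.
    nsites:
        Number of sites the matrix was built from, if known.
    """

    id: str
    name: str
    alphabet: str
    probs: np.ndarray
    nsites: Optional[int] = None

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if not self.id:
            raise ValueError("motif id must be non-empty")
        if self.alphabet not in (DNA, RNA):
            raise ValueError(f"unsupported alphabet {self.alphabet!r}")
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError(
                f"motif {self.id}: probs must be a (width, 4) matrix with width >= 1"
            )
        if np.any(probs < 0):
            raise ValueError(f"motif {self.id}: negative probabilities")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(
                f"motif {self.id}: row {bad} sums to {sums[bad]:.6g}, expected 1"
            )
        if self.nsites is not None and self.nsites <= 0:
            raise ValueError(f"motif {self.id}: nsites must be positive")

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        """Majority-letter consensus string."""
        return "".join(self.alphabet[i] for i in np.argmax(self.probs, axis=1))

    def __eq__(self, other) -> bool:
        if not isinstance(other, Motif):
            return NotImplemented
        return (
            self.id == other.id
            and self.name == other.name
            and self.alphabet == other.alphabet
            and self.nsites == other.nsites
            and self.probs.shape == other.probs.shape
            and np.allclose(self.probs, other.probs, rtol=0, atol=1e-9)
        )


@dataclass(frozen=True)
class Background:
    """0-order letter frequencies used to define log-odds scores."""

    freqs: np.ndarray

    def __post_init__(self):
        freqs = np.asarray(self.freqs, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        if freqs.shape != (4,):
            raise ValueError("background needs exactly 4 frequencies")
        if np.any(freqs <= 0):
            raise ValueError("background frequencies must be strictly positive")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"background frequencies sum to {freqs.sum()!r}, not 1")

    @classmethod
    def uniform(cls) -> "Background":
        return cls(np.full(4, 0.25))


@dataclass(frozen=True)
class ScoringMatrix:
    """Log-odds matrix in bits, one row per motif position."""

    motif_id: str
    scores: np.ndarray
    strand: str = "+"
    alphabet: str = DNA

    def __post_init__(self):
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 4:
            raise ValueError("scores must be a (width, 4) matrix")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite (use the negative sentinel)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def width(self) -> int:
        return self.scores.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())


# ---------------------------------------------------------------------------
# MEME format (minimal dialect: version, ALPHABET, strands, background
# frequencies, MOTIF blocks with letter-probability matrices)
# ---------------------------------------------------------------------------

_LPM_RE = re.compile(r"letter-probability matrix:?(?P<rest>.*)", re.IGNORECASE)
_KV_RE = re.compile(r"(\w+)\s*=\s*(\S+)")


class MemeParseError(ValueError):
    pass


def parse_meme_motifs(text: str) -> list[Motif]:
    """Parse motifs from a MEME-format document.

    Only the letter-probability subset of the format is read; other
    blocks are skipped with a logged warning.  Matrix rows whose sum is
    within 1e-3 of 1 are renormalised to sum exactly 1; larger
    discrepancies raise :class:`MemeParseError`.
    """
    lines = text.splitlines()
    if not any(re.match(r"^\s*MEME version", ln, re.IGNORECASE) for ln in lines):
        raise MemeParseError("missing 'MEME version' line")
    alphabet = DNA
    motifs: list[Motif] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line.upper().startswith("ALPHABET"):
            letters = line.split("=", 1)[-1].strip().upper()
            if letters in (DNA, RNA):
                alphabet = letters
            else:
                raise MemeParseError(f"unsupported ALPHABET {letters!r}")
            i += 1
        elif line.startswith("MOTIF"):
            tokens = line.split()
            if len(tokens) < 2:
                raise MemeParseError("MOTIF line without an identifier")
            motif_id = tokens[1]
            name = tokens[2] if len(tokens) > 2 else motif_id
            i += 1
            # find the letter-probability header for this block
            while i < n and not _LPM_RE.match(lines[i].strip()):
                if lines[i].strip().startswith("MOTIF"):
                    raise MemeParseError(
                        f"motif {motif_id}: no letter-probability matrix"
                    )
                i += 1
            if i == n:
                raise MemeParseError(f"motif {motif_id}: no letter-probability matrix")
            header = _LPM_RE.match(lines[i].strip()).group("rest")
            kv = dict(_KV_RE.findall(header))
            declared_w = int(kv["w"]) if "w" in kv else None
            alength = int(kv["alength"]) if "alength" in kv else 4
            nsites = None
            if "nsites" in kv:
                nsites = max(1, int(round(float(kv["nsites"]))))
            if alength != 4:
                raise MemeParseError(
                    f"motif {motif_id}: alength={alength} unsupported (need 4)"
                )
            i += 1
            rows: list[list[float]] = []
            while i < n:
                row_line = lines[i].strip()
                if not row_line or not re.match(r"^[\d.eE+\-\s]+$", row_line):
                    break
                vals = [float(x) for x in row_line.split()]
                if len(vals) != 4:
                    raise MemeParseError(
                        f"motif {motif_id}: matrix row {len(rows)} has "
                        f"{len(vals)} columns, expected 4"
                    )
                rows.append(vals)
                i += 1
            if declared_w is not None and declared_w != len(rows):
                raise MemeParseError(
                    f"motif {motif_id}: header declares w={declared_w} but "
                    f"{len(rows)} rows found"
                )
            if not rows:
                raise MemeParseError(f"motif {motif_id}: empty matrix")
            probs = np.array(rows, dtype=float)
            sums = probs.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-3):
                bad = int(np.argmax(np.abs(sums - 1.0)))
                raise MemeParseError(
                    f"motif {motif_id}: row {bad} sums to {sums[bad]:.6g} "
                    "(off by more than 1e-3)"
                )
            probs = probs / sums[:, None]
            motifs.append(Motif(motif_id, name, alphabet, probs, nsites))
        else:
            if line and not line.lower().startswith(
                ("meme version", "strands", "background", "alphabet")
            ) and not re.match(r"^[\d.eE+\-\s]+$", line):
                log.warning("ignoring unsupported MEME block line: %s", line[:60])
            i += 1
    return motifs


def write_meme_motifs(motifs: Iterable[Motif], background: Background | None = None) -> str:
    """Serialise motifs back to the minimal MEME dialect."""
    motifs = list(motifs)
    alphabet = motifs[0].alphabet if motifs else DNA
    out = ["MEME version 4", "", f"ALPHABET= {alphabet}", ""]
    if alphabet == DNA:
        out += ["strands: + -", ""]
    if background is not None:
        pairs = " ".join(
            f"{letter} {freq:.6f}" for letter, freq in zip(alphabet, background.freqs)
        )
        out += ["Background letter frequencies", pairs, ""]
    for m in motifs:
        out.append(f"MOTIF {m.id} {m.name}")
        header = f"letter-probability matrix: alength= 4 w= {m.width}"
        if m.nsites is not None:
            header += f" nsites= {m.nsites}"
        out.append(header)
        for row in m.probs:
            out.append(" ".join(f"{x:.10g}" for x in row))
        out.append("")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Background estimation and log-odds conversion
# ---------------------------------------------------------------------------


def compute_background(*seq_sets, floor: float = 1e-3) -> Background:
    """0-order background frequencies from one or more sequence sets.

    DNA counts are symmetrised over both strands (A with T, C with G);
    RNA is counted single-stranded.  Ambiguous letters are excluded.
    Each frequency is floored at `floor` and the vector renormalised.
    """
    counts = np.zeros(4, dtype=float)
    is_rna = False
    for sset in seq_sets:
        if sset is None:
            continue
        alpha = getattr(sset, "alphabet", DNA)
        is_rna = is_rna or alpha == RNA
        for _, seq in sset.records:
            for j, letter in enumerate(alpha):
                counts[j] += seq.count(letter)
    if counts.sum() == 0:
        raise ValueError("sequences contain only ambiguous letters")
    if not is_rna:
        counts = np.array(
            [counts[0] + counts[3], counts[1] + counts[2],
             counts[2] + counts[1], counts[3] + counts[0]],
            dtype=float,
        )
    freqs = counts / counts.sum()
    freqs = np.maximum(freqs, floor)
    freqs = freqs / freqs.sum()
    return Background(freqs)


def to_log_odds(motif: Motif, bg: Background, pseudo: float = 0.1) -> ScoringMatrix:
    """Convert a PPM to a log2-odds scoring matrix (bits).

    The pseudocount is distributed proportionally to the background:
    ``score[i][a] = log2((p[i][a]*n + pseudo*bg[a]) / ((n + pseudo)*bg[a]))``
    with ``n`` the effective site count (``nsites`` or 100).  With
    ``pseudo=0`` a zero probability yields the negative sentinel.
    """
    if pseudo < 0:
        raise ValueError("pseudo must be >= 0")
    nsites_eff = motif.nsites if motif.nsites is not None else 100
    num = motif.probs * nsites_eff + pseudo * bg.freqs[None, :]
    den = (nsites_eff + pseudo) * bg.freqs[None, :]
    with np.errstate(divide="ignore"):
        scores = np.log2(num / den)
    scores = np.where(np.isneginf(scores), NEG_SENTINEL, scores)
    return ScoringMatrix(motif.id, scores, "+", motif.alphabet)


def reverse_complement_matrix(sm: ScoringMatrix) -> ScoringMatrix:
    """Reverse-complement a DNA scoring matrix (involution)."""
    if sm.alphabet != DNA:
        raise ValueError("reverse complement is undefined for RNA matrices")
    flipped = sm.scores[::-1, :][:, _COMPLEMENT_ORDER]
    strand = "-" if sm.strand == "+" else "+"
    return ScoringMatrix(sm.motif_id, flipped, strand, sm.alphabet)


def motif_from_consensus(
    consensus: str,
    p_match: float = 0.85,
    motif_id: str | None = None,
    name: str | None = None,
    alphabet: str = DNA,
    nsites: int = 100,
) -> Motif:
    """Build a motif whose columns put `p_match` on the consensus letter.

    Convenient for constructing synthetic motifs of controlled
    information content; off-consensus letters share the remainder.
    """
    consensus = consensus.upper()
    if not 0.25 <= p_match <= 1.0:
        raise ValueError("p_match must be in [0.25, 1]")
    probs = np.full((len(consensus), 4), (1.0 - p_match) / 3.0)
    for i, letter in enumerate(consensus):
        j = alphabet.index(letter)
        probs[i, j] = p_match
    motif_id = motif_id or consensus
    return Motif(motif_id, name or motif_id, alphabet, probs, nsites)
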