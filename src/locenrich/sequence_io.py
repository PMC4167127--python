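"""Equal-length sequence sets read from FASTA.

The statistical model treats every sequence as an aligned window (e.g.
a peak-centered or TSS-centered region), so all sequences in a set must
have identical length, and when a primary and a control set are
analysed together their lengths must match as well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_model import DNA, RNA

log = logging.getLogger(__name__)

_VALID = set("ACGTUN")


@dataclass
class SequenceSet:
    """An ordered set of equal-length sequences with a primary/control role."""

    records: list[tuple[str, str]]
    role: str = "primary"

    def __post_init__(self):
        if self.role not in ("primary", "control"):
            raise ValueError(f"role must be primary or control, got {self.role!r}")
        if not self.records:
            raise ValueError("sequence set is empty")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            offenders = sorted(
                {rid for rid, seq in self.records
                 if len(seq) != len(self.records[0][1])}
            )
            raise ValueError(
                "sequences must all have the same length; offending ids: "
                + ", ".join(offenders[:10])
            )
        if lengths == {0}:
            raise ValueError("sequences must have length >= 1")
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            seen, dups = set(), []
            for rid in ids:
                if rid in seen:
                    dups.append(rid)
                seen.add(rid)
            raise ValueError(f"duplicate sequence ids: {', '.join(dups[:10])}")
        has_t = any("T" in seq for _, seq in self.records)
        has_u = any("U" in seq for _, seq in self.records)
        if has_t and has_u:
            raise ValueError("set mixes T and U; cannot decide DNA vs RNA")

    @property
    def length(self) -> int:
        """Common sequence length L in bp."""
        return len(self.records[0][1])

    @property
    def alphabet(self) -> str:
        return RNA if any("U" in seq for _, seq in self.records) else DNA

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _clean(seq: str, counter: dict) -> str:
    seq = seq.upper()
    cleaned = []
    for ch in seq:
        if ch in _VALID:
            cleaned.append(ch)
        else:
            counter["n"] = counter.get("n", 0) + 1
            cleaned.append("N")
    return "".join(cleaned)


def read_fasta(path, role: str = "primary") -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Sequences are uppercased; ambiguity codes other than N are mapped to
    N (count logged).  Validation (equal lengths, unique ids, T/U
    consistency) happens in the SequenceSet constructor.
    """
    counter: dict = {}
    records = [
        (rec.id, _clean(str(rec.seq), counter))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    if counter.get("n"):
        log.warning(
            "%s: %d non-ACGTUN letters mapped to N", path, counter["n"]
        )
    return SequenceSet(records, role=role)


def write_fasta(sset: SequenceSet, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in sset.records
    ]
    SeqIO.write(recs, str(path), "fasta")


def check_compatible(primary: SequenceSet, control: SequenceSet) -> None:
    """Primary and control sets must share L (regions at identical coordinates)."""
    if primary.length != control.length:
        raise ValueError(
            f"primary length {primary.length} != control length {control.length}"
        )
    if primary.alphabet != control.alphabet:
        raise ValueError("primary and control sets use different alphabets")
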