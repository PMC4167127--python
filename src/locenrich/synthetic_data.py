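"""Synthetic sequence sets with planted motif sites.

Emulates the aligned-window designs the statistics target: a primary
set whose motif sites pile up at a preferred location (e.g. Gaussian
around the window center, as in ChIP-seq peak regions) versus a control
set with uniformly placed or absent sites.  Every generator is
deterministic per seed, and the planted ground truth is recorded so
recovery can be scored exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .motif_model import DNA, Background, Motif, motif_from_consensus
from .sequence_io import SequenceSet, write_fasta

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGT", "TGCA")

#: Study conditions for the paired fixtures: number of sequences and
#: window length mirror 500 bp peak-centered region sets; occupancy and
#: positional spread are the fixture's defining parameters.
FIXTURE_S = 500
FIXTURE_L = 500
FIXTURE_OCCUPANCY = 0.6
FIXTURE_SIGMA = 30.0

SCENARIOS = ("differential-central", "null", "swapped")


def example_motif() -> Motif:
    """The default planted motif: an AP-1-like 10 bp consensus.

    0.85 on the consensus letter per column (~1.15 bits/column) makes
    sampled sites score well above the 5-bit default threshold while
    remaining realistically degenerate.
    """
    return motif_from_consensus(
        "TGACTCATGC", p_match=0.85, motif_id="PLANT1", name="planted_ap1_like"
    )


def decoy_motifs(n: int, width: int = 10, seed: int = 0) -> list[Motif]:
    """Random-consensus decoys for rank and specificity tests."""
    rng = np.random.default_rng(seed)
    motifs = []
    for i in range(n):
        consensus = "".join(rng.choice(list(DNA), size=width))
        motifs.append(
            motif_from_consensus(
                consensus, p_match=0.85, motif_id=f"DECOY{i+1}",
                name=f"decoy_{consensus}",
            )
        )
    return motifs


@dataclass(frozen=True)
class PlantSpec:
    """How to plant one motif into a sequence set.

    placement: "uniform", "gaussian" (center offset mu bp from the
    sequence center, sd sigma bp) or "fixed" (exact start offset).
    """

    motif: Motif
    occupancy: float
    placement: str = "uniform"
    mu: float = 0.0
    sigma: float = FIXTURE_SIGMA
    offset: Optional[int] = None
    strands: str = "both"
    consensus_only: bool = False

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if self.placement not in ("uniform", "gaussian", "fixed"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.placement == "gaussian" and self.sigma <= 0:
            raise ValueError("gaussian placement needs sigma > 0")
        if self.placement == "fixed" and self.offset is None:
            raise ValueError("fixed placement needs an offset")
        if self.strands not in ("both", "forward"):
            raise ValueError("strands must be 'both' or 'forward'")


@dataclass
class PlantedTruth:
    """Per-sequence ground truth: (seq_id, planted, start, strand)."""

    records: list[tuple[str, bool, Optional[int], Optional[str]]]

    def planted_count(self) -> int:
        return sum(1 for _, planted, _, _ in self.records if planted)

    def to_tsv(self) -> str:
        lines = ["#seq_id\tplanted\tstart\tstrand"]
        for rid, planted, start, strand in self.records:
            lines.append(
                f"{rid}\t{int(planted)}\t{'' if start is None else start}"
                f"\t{'' if strand is None else strand}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "PlantedTruth":
        records = []
        for line in text.splitlines():
            if not line or line.startswith("#"):
                continue
            rid, planted, start, strand = line.split("\t")
            records.append(
                (
                    rid,
                    bool(int(planted)),
                    int(start) if start else None,
                    strand or None,
                )
            )
        return cls(records)


def generate_background_set(
    S: int,
    L: int,
    composition: Background | None = None,
    seed: int = 0,
    role: str = "primary",
    prefix: str = "seq",
) -> SequenceSet:
    """S i.i.d. random sequences of length L from a 0-order composition."""
    if S < 1 or L < 1:
        raise ValueError("need S >= 1 and L >= 1")
    composition = composition or Background.uniform()
    rng = np.random.default_rng(seed)
    letters = np.array(list(DNA))
    records = []
    for i in range(S):
        seq = "".join(rng.choice(letters, size=L, p=composition.freqs))
        records.append((f"{prefix}_{i}", seq))
    return SequenceSet(records, role=role)


def _sample_site(motif: Motif, rng: np.random.Generator, consensus_only: bool) -> str:
    if consensus_only:
        return motif.consensus
    letters = list(motif.alphabet)
    return "".join(
        rng.choice(letters, p=motif.probs[i]) for i in range(motif.width)
    )


def _sample_start(
    spec: PlantSpec, L: int, w: int, rng: np.random.Generator
) -> int:
    max_start = L - w
    if spec.placement == "uniform":
        return int(rng.integers(0, max_start + 1))
    if spec.placement == "fixed":
        if not 0 <= spec.offset <= max_start:
            raise ValueError(
                f"fixed offset {spec.offset} out of range [0, {max_start}]"
            )
        return spec.offset
    # gaussian placement of the site CENTER relative to the sequence
    # center; out-of-range draws are resampled (not clipped) so the
    # edges do not accumulate artificial pile-ups
    seq_center = (L - 1) / 2.0
    for _ in range(10000):
        center = seq_center + spec.mu + rng.normal(0.0, spec.sigma)
        start = int(round(center - (w - 1) / 2.0))
        if 0 <= start <= max_start:
            return start
    raise RuntimeError("gaussian placement failed to find a valid start")


def plant_motifs(
    seqs: SequenceSet, spec: PlantSpec, seed: int = 0
) -> tuple[SequenceSet, PlantedTruth]:
    """Plant one sampled motif site per sequence with probability occupancy.

    Sites are sampled from the probability matrix (so match-score
    distributions are realistic) and inserted by substring replacement;
    '-' strand plants insert the reverse complement.
    """
    w = spec.motif.width
    if seqs.length < w:
        raise ValueError("sequences shorter than motif width")
    rng = np.random.default_rng(seed)
    new_records = []
    truth = []
    for rid, seq in seqs.records:
        if rng.random() < spec.occupancy:
            start = _sample_start(spec, seqs.length, w, rng)
            site = _sample_site(spec.motif, rng, spec.consensus_only)
            strand = "+"
            if spec.strands == "both" and rng.random() < 0.5:
                strand = "-"
                site = site.translate(_RC)[::-1]
            seq = seq[:start] + site + seq[start + w :]
            truth.append((rid, True, start, strand))
        else:
            truth.append((rid, False, None, None))
        new_records.append((rid, seq))
    return SequenceSet(new_records, role=seqs.role), PlantedTruth(truth)


def make_scenario_sets(
    scenario: str,
    motif: Motif | None = None,
    S: int = FIXTURE_S,
    L: int = FIXTURE_L,
    occupancy: float = FIXTURE_OCCUPANCY,
    sigma: float = FIXTURE_SIGMA,
    composition: Background | None = None,
    seed: int = 0,
) -> tuple[SequenceSet, SequenceSet, PlantedTruth, PlantedTruth]:
    """Build in-memory primary/control sets for a named scenario.

    differential-central: primary planted Gaussian(mu=0, sigma) around
    the center, control planted uniformly, equal occupancy; null: both
    uniform; swapped: the differential-central roles exchanged.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    motif = motif or example_motif()
    central = PlantSpec(motif, occupancy, "gaussian", mu=0.0, sigma=sigma)
    uniform = PlantSpec(motif, occupancy, "uniform")
    if scenario == "differential-central":
        primary_spec, control_spec = central, uniform
    elif scenario == "swapped":
        primary_spec, control_spec = uniform, central
    else:
        primary_spec, control_spec = uniform, uniform
    raw_primary = generate_background_set(
        S, L, composition, seed=seed, role="primary", prefix="pri"
    )
    raw_control = generate_background_set(
        S, L, composition, seed=seed + 1_000_003, role="control", prefix="ctl"
    )
    primary, truth_p = plant_motifs(raw_primary, primary_spec, seed=seed + 1)
    control, truth_c = plant_motifs(raw_control, control_spec, seed=seed + 2)
    return primary, control, truth_p, truth_c


def make_paired_fixture(
    scenario: str,
    out_dir,
    motif: Motif | None = None,
    S: int = FIXTURE_S,
    L: int = FIXTURE_L,
    occupancy: float = FIXTURE_OCCUPANCY,
    sigma: float = FIXTURE_SIGMA,
    seed: int = 0,
) -> dict[str, Path]:
    """Write primary/control FASTA files plus a truth sidecar TSV.

    The sidecar records, for every sequence in both sets, whether a
    site was planted and where.  Same seed, same bytes.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    primary, control, truth_p, truth_c = make_scenario_sets(
        scenario, motif, S, L, occupancy, sigma, seed=seed
    )
    paths = {
        "primary": out_dir / "primary.fa",
        "control": out_dir / "control.fa",
        "truth": out_dir / "truth.tsv",
    }
    write_fasta(primary, paths["primary"])
    write_fasta(control, paths["control"])
    truth_text = "#set\tseq_id\tplanted\tstart\tstrand\n"
    for set_name, truth in (("primary", truth_p), ("control", truth_c)):
        for rid, planted, start, strand in truth.records:
            truth_text += (
                f"{set_name}\t{rid}\t{int(planted)}"
                f"\t{'' if start is None else start}"
                f"\t{'' if strand is None else strand}\n"
            )
    paths["truth"].write_text(truth_text)
    return paths
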