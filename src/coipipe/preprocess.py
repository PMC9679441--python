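"""Read preprocessing: quality filtering, primer trimming, pair merging.

The target amplicon is the 313 bp Leray cox1 fragment; after demultiplexing,
each mate begins with a degenerate PCR primer, the insert is read from both
ends by 2x300 chemistry, and valid merged amplicons are exactly 313 nt.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from coipipe.seqio import IUPAC_CHARS, ReadPair, SequenceRecord

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Amplicon-specific parts of the mlCOIintF / jgHCO2198-style primer pair used
# for the 313 bp fragment (linker tails for the second PCR excluded).
DEFAULT_FWD_PRIMER = "GGWACWGGWTGAACWGTWTAYCCYCC"
DEFAULT_REV_PRIMER = "TAHACTTCNGGGTGKCCRAARAATCA"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """Degenerate forward/reverse primers (amplicon-specific parts only)."""

    fwd: str = DEFAULT_FWD_PRIMER
    rev: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        for name, primer in (("fwd", self.fwd), ("rev", self.rev)):
            bad = set(primer) - IUPAC_CHARS
            if bad:
                raise ValueError(f"{name} primer contains non-IUPAC characters {bad}")


@dataclass(frozen=True)
class MergedAmplicon:
    """A merged read pair: consensus sequence plus consensus Phred vector."""

    id: str
    seq: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError("sequence/quality length mismatch")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FilterConfig:
    """Preprocessing thresholds.

    min_quality: Phred threshold for the per-mate quality filter (default 20,
        i.e. reads with quality scores below 20 are discarded).
    quality_policy: 'mean' (mean Phred of a mate), 'min' (worst base), or
        'window' (mean over any sliding window of ``window_size``).
    target_length: retained merged length in nt (default 313).
    min_overlap / max_overlap_mismatch_frac: pair-merge acceptance bounds.
    drop_n: remove amplicons containing N during length selection.
    """

    min_quality: int = 20
    quality_policy: str = "mean"
    target_length: int = 313
    min_overlap: int = 20
    max_overlap_mismatch_frac: float = 0.1
    drop_n: bool = True
    window_size: int = 25

    def __post_init__(self) -> None:
        if self.min_quality <= 0 or self.target_length <= 0 or self.min_overlap <= 0:
            raise ValueError("thresholds must be positive")
        if not 0.0 <= self.max_overlap_mismatch_frac <= 1.0:
            raise ValueError("max_overlap_mismatch_frac must lie in [0, 1]")
        if self.quality_policy not in ("mean", "min", "window"):
            raise ValueError(f"unknown quality policy {self.quality_policy!r}")


def iupac_match(pattern_base: str, observed_base: str) -> bool:
    """True iff the observed base is within the degeneracy set of the pattern.

    An observed ``N`` (unknown base) is matched only by a fully degenerate
    pattern position (``N``).
    """
    try:
        pattern_set = IUPAC_SETS[pattern_base]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {pattern_base!r}") from None
    if observed_base == "N":
        return pattern_set == IUPAC_SETS["N"]
    return observed_base in pattern_set


def _mismatches(pattern: str, window: str, limit: int) -> int:
    """IUPAC-aware mismatch count, short-circuiting past ``limit``."""
    n = 0
    for p, o in zip(pattern, window):
        if not iupac_match(p, o):
            n += 1
            if n > limit:
                return n
    return n


def quality_filter(pair: ReadPair, cfg: FilterConfig) -> bool:
    """Return True (keep) iff both mates pass the configured quality policy."""
    for mate in (pair.fwd, pair.rev):
        if mate.qual is None:
            raise ValueError(f"read {mate.id!r} has no qualities")
        q = np.asarray(mate.qual, dtype=float)
        if cfg.quality_policy == "mean":
            if q.mean() < cfg.min_quality:
                return False
        elif cfg.quality_policy == "min":
            if q.min() < cfg.min_quality:
                return False
        else:  # window
            w = min(cfg.window_size, len(q))
            means = np.convolve(q, np.ones(w) / w, mode="valid")
            if means.min() < cfg.min_quality:
                return False
    return True


def find_primer(seq: str, primer: str, max_mismatch: int, max_leading: int = 0) -> int | None:
    """Locate the primer start position at/near the 5' end; None if absent.

    Scans start offsets 0..max_leading and returns the first offset with at
    most ``max_mismatch`` IUPAC-aware mismatches (smallest mismatch count
    wins among scanned offsets, earlier offset breaking ties).
    """
    best: tuple[int, int] | None = None
    for off in range(0, max_leading + 1):
        if off + len(primer) > len(seq):
            break
        mm = _mismatches(primer, seq[off : off + len(primer)], max_mismatch)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, off)
            if mm == 0:
                break
    return None if best is None else best[1]


def trim_primers(
    record: SequenceRecord,
    primers: PrimerPair,
    max_mismatch: int = 2,
    max_leading: int = 0,
) -> SequenceRecord | None:
    """Excise the insert between the forward primer (5') and the reverse
    complement of the reverse primer (3') of a full-length amplicon.

    Returns None (reject) when either primer site is not found within
    ``max_mismatch`` IUPAC-aware mismatches.
    """
    start = find_primer(record.seq, primers.fwd, max_mismatch, max_leading)
    if start is None:
        return None
    insert_start = start + len(primers.fwd)
    rc_rev = reverse_complement(primers.rev)
    tail_start = len(record.seq) - len(rc_rev)
    if tail_start < insert_start:
        return None
    if _mismatches(rc_rev, record.seq[tail_start:], max_mismatch) > max_mismatch:
        return None
    if tail_start == insert_start:
        return None  # empty insert
    qual = record.qual[insert_start:tail_start] if record.qual is not None else None
    return SequenceRecord(record.id, record.seq[insert_start:tail_start], qual)


def trim_pair_primers(
    pair: ReadPair,
    primers: PrimerPair,
    max_mismatch: int = 2,
    max_leading: int = 0,
) -> ReadPair | None:
    """Strip each mate's 5'-end primer (forward primer on the forward mate,
    reverse primer on the reverse mate); None when either is missing."""
    trimmed = []
    for mate, primer in ((pair.fwd, primers.fwd), (pair.rev, primers.rev)):
        start = find_primer(mate.seq, primer, max_mismatch, max_leading)
        if start is None:
            return None
        cut = start + len(primer)
        if cut >= len(mate.seq):
            return None
        trimmed.append(
            SequenceRecord(mate.id, mate.seq[cut:], mate.qual[cut:] if mate.qual else None)
        )
    return ReadPair(trimmed[0], trimmed[1])


def merge_pair(pair: ReadPair, cfg: FilterConfig) -> MergedAmplicon | None:
    """Merge a read pair over its best ungapped 3' overlap.

    The reverse mate is reverse-complemented; candidate overlap lengths are
    scored by match count (largest overlap breaking ties).  The merge is
    rejected when the best overlap is shorter than ``cfg.min_overlap`` or its
    mismatch fraction exceeds ``cfg.max_overlap_mismatch_frac``.  At each
    overlap position the base with the higher Phred wins and the consensus
    quality is the maximum of the two.
    """
    fwd_seq = np.frombuffer(pair.fwd.seq.encode(), dtype=np.uint8)
    rc_rev = reverse_complement(pair.rev.seq)
    rev_seq = np.frombuffer(rc_rev.encode(), dtype=np.uint8)
    fwd_q = np.asarray(pair.fwd.qual, dtype=np.int16)
    rev_q = np.asarray(pair.rev.qual, dtype=np.int16)[::-1]

    max_o = min(len(fwd_seq), len(rev_seq))
    best_o, best_matches = 0, -1
    for o in range(cfg.min_overlap, max_o + 1):
        matches = int(np.count_nonzero(fwd_seq[len(fwd_seq) - o :] == rev_seq[:o]))
        if matches >= best_matches:  # >= : larger overlap wins ties
            best_o, best_matches = o, matches
    if best_o < cfg.min_overlap or best_matches < 0:
        return None
    mismatch_frac = (best_o - best_matches) / best_o
    if mismatch_frac > cfg.max_overlap_mismatch_frac:
        return None

    o = best_o
    f_tail = fwd_seq[len(fwd_seq) - o :]
    r_head = rev_seq[:o]
    fq_tail = fwd_q[len(fwd_q) - o :]
    rq_head = rev_q[:o]
    take_fwd = fq_tail >= rq_head
    cons = np.where(take_fwd, f_tail, r_head)
    cons_q = np.maximum(fq_tail, rq_head)

    seq = pair.fwd.seq[: len(fwd_seq) - o] + cons.tobytes().decode() + rc_rev[o:]
    qual = tuple(int(q) for q in np.concatenate([fwd_q[: len(fwd_q) - o], cons_q, rev_q[o:]]))
    return MergedAmplicon(pair.fwd.id, seq, qual)


def length_select(
    amplicons: Iterable[MergedAmplicon],
    target_length: int = 313,
    drop_n: bool = True,
) -> list[MergedAmplicon]:
    """Retain amplicons of exactly the target length (order preserved);
    amplicons containing N are also removed when ``drop_n``."""
    out = []
    for amp in amplicons:
        if len(amp) != target_length:
            continue
        if drop_n and "N" in amp.seq:
            continue
        out.append(amp)
    return out


def preprocess_pairs(
    pairs: Sequence[ReadPair],
    primers: PrimerPair,
    cfg: FilterConfig,
    max_primer_mismatch: int = 2,
    max_leading: int = 0,
) -> tuple[list[MergedAmplicon], dict[str, int]]:
    """Run quality filter -> per-mate primer trim -> merge -> length select.

    Returns the surviving amplicons and a funnel of per-stage read counts.
    """
    funnel = {"input": len(pairs)}
    kept = [p for p in pairs if quality_filter(p, cfg)]
    funnel["quality_filtered"] = len(kept)
    trimmed = [
        t for p in kept
        if (t := trim_pair_primers(p, primers, max_primer_mismatch, max_leading)) is not None
    ]
    funnel["primer_trimmed"] = len(trimmed)
    merged = [m for p in trimmed if (m := merge_pair(p, cfg)) is not None]
    funnel["merged"] = len(merged)
    selected = length_select(merged, cfg.target_length, cfg.drop_n)
    funnel["length_selected"] = len(selected)
    return selected, funnel
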