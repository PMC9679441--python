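"""Sequence I/O and demultiplexing.

FASTQ (Phred+33) reading via Biopython, paired-stream pairing checks,
exact-match inline-tag demultiplexing, and FASTA round-tripping with the
de-facto amplicon abundance annotation ``;size=N`` in headers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator
from Bio.SeqIO.FastaIO import SimpleFastaParser

IUPAC_CHARS = set("ACGTRYSWKMBDHVN")
_TAG_ALPHABET = set("ACGT")


class FastqParseError(ValueError):
    """Malformed FASTQ record, reported with an approximate line number."""


class PairingError(ValueError):
    """Forward/reverse FASTQ streams disagree in length or record ids."""


class ManifestError(ValueError):
    """Invalid sample manifest (duplicate or malformed tags)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with optional Phred qualities."""

    id: str
    seq: str
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.qual is not None:
            if len(self.qual) != len(self.seq):
                raise ValueError(
                    f"record {self.id!r}: quality length {len(self.qual)} != "
                    f"sequence length {len(self.seq)}"
                )
            if any(q < 0 or q > 60 for q in self.qual):
                raise ValueError(f"record {self.id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class ReadPair:
    """One forward/reverse read pair from a sequencing cluster."""

    fwd: SequenceRecord
    rev: SequenceRecord

    def __post_init__(self) -> None:
        if self.fwd.qual is None or self.rev.qual is None:
            raise ValueError("both mates of a ReadPair must carry qualities")


@dataclass(frozen=True)
class SampleManifest:
    """Mapping of sample ids to unique 8-nt inline index tags."""

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        tags = [tag for _, tag in self.entries]
        for tag in tags:
            if len(tag) != 8 or not set(tag) <= _TAG_ALPHABET:
                raise ManifestError(f"tag {tag!r} is not an 8-nt A/C/G/T string")
        if len(set(tags)) != len(tags):
            dupes = sorted({t for t in tags if tags.count(t) > 1})
            raise ManifestError(f"duplicate tags in manifest: {dupes}")

    @property
    def tag_to_sample(self) -> dict[str, str]:
        return {tag: sample for sample, tag in self.entries}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        """Read a two-column TSV with header ``sample_id<TAB>tag``."""
        entries = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sample_id", "tag"]:
                raise ManifestError(
                    f"{path}: expected columns sample_id, tag; got {header}"
                )
            for line in fh:
                if not line.strip():
                    continue
                sample, tag = line.rstrip("\n").split("\t")[:2]
                entries.append((sample, tag))
        return cls(tuple(entries))


_MATE_SUFFIX = re.compile(r"(/[12]$)|(\s[12]:.*$)")


def _core_id(read_id: str) -> str:
    """Strip common mate suffixes: 'r1/1' -> 'r1', 'r1 1:N:0:X' -> 'r1'."""
    return _MATE_SUFFIX.sub("", read_id)


def _iter_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    n = 0
    try:
        with open(path) as fh:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                if len(seq) != len(qual):
                    raise FastqParseError(
                        f"{path}: record near line {4 * n - 3}: sequence and "
                        f"quality lengths differ"
                    )
                phred = tuple(ord(c) - 33 for c in qual)
                yield SequenceRecord(title.split()[0] + _mate_tail(title), seq.upper(), phred)
    except ValueError as exc:
        if isinstance(exc, (FastqParseError, PairingError)):
            raise
        raise FastqParseError(f"{path}: near line {4 * n + 1}: {exc}") from exc


def _mate_tail(title: str) -> str:
    """Preserve an Illumina-style ' 1:...' mate marker as part of the id."""
    parts = title.split(None, 1)
    if len(parts) == 2 and re.match(r"^[12]:", parts[1]):
        return " " + parts[1]
    return ""


def read_fastq_pairs(path_fwd: str | Path, path_rev: str | Path) -> Iterator[ReadPair]:
    """Stream matched read pairs from two FASTQ files in file order.

    Record ids of a pair must agree up to the usual mate suffixes
    (``/1``, ``/2`` or Illumina ``1:...``/``2:...`` descriptions).
    """
    it_f, it_r = _iter_fastq(path_fwd), _iter_fastq(path_rev)
    n = 0
    while True:
        fwd = next(it_f, None)
        rev = next(it_r, None)
        if fwd is None and rev is None:
            return
        if fwd is None or rev is None:
            raise PairingError(
                f"unequal record counts: one file ends after {n} records"
            )
        n += 1
        if _core_id(fwd.id) != _core_id(rev.id):
            raise PairingError(
                f"pair {n}: mate ids disagree ({fwd.id!r} vs {rev.id!r})"
            )
        yield ReadPair(fwd, rev)


@dataclass
class DemuxResult:
    """Per-sample read-pair bins plus the unassigned bin."""

    bins: dict[str, list[ReadPair]] = field(default_factory=dict)
    unassigned: list[ReadPair] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(len(v) for v in self.bins.values()) + len(self.unassigned)


def demultiplex(pairs: Iterable[ReadPair], manifest: SampleManifest) -> DemuxResult:
    """Assign pairs to samples by exact match of the first 8 forward bases.

    The matched tag is removed from the assigned forward read (sequence and
    qualities); unmatched pairs land unmodified in the unassigned bin.  Every
    input pair appears in exactly one output bin.
    """
    if not manifest.entries:
        raise ManifestError("empty manifest")
    tag_to_sample = manifest.tag_to_sample
    result = DemuxResult(bins={sample: [] for sample, _ in manifest.entries})
    for pair in pairs:
        tag = pair.fwd.seq[:8]
        sample = tag_to_sample.get(tag)
        if sample is None or len(pair.fwd.seq) <= 8:
            result.unassigned.append(pair)
            continue
        trimmed = SequenceRecord(
            pair.fwd.id, pair.fwd.seq[8:], pair.fwd.qual[8:] if pair.fwd.qual else None
        )
        result.bins[sample].append(ReadPair(trimmed, pair.rev))
    return result


_SIZE_RE = re.compile(r";size=(\d+)$")


def write_fasta(records: Iterable[tuple[str, str, int]], path: str | Path) -> None:
    """Write ``(id, seq, count)`` records as FASTA with ``;size=N`` headers."""
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec_id, seq, count in records:
            if rec_id in seen:
                raise ValueError(f"duplicate record id {rec_id!r}")
            seen.add(rec_id)
            fh.write(f">{rec_id};size={count}\n{seq}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str, int]]:
    """Read FASTA written by :func:`write_fasta`; missing ``;size=`` means 1."""
    out = []
    with open(path) as fh:
        for title, seq in SimpleFastaParser(fh):
            name = title.split()[0]
            m = _SIZE_RE.search(name)
            count = int(m.group(1)) if m else 1
            out.append((_SIZE_RE.sub("", name), seq.upper(), count))
    return out


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records with qualities as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")
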