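"""Abundance-aware single-nucleotide-difference OTU clustering.

The core algorithm: merged amplicons of one fixed length are dereplicated at
100% identity into unique groups with read counts, groups below a minimum
count (default 3 reads) are discarded, and groups at Hamming distance 1 are
combined into OTUs.  The default merge policy walks groups in decreasing
abundance and attaches each group to its most abundant already-assigned
neighbour whose count is at least its own, so low-count sequencing-error
variants are absorbed by their parent haplotypes while equally abundant
distinct haplotypes stay apart.  A pure connected-components policy (merge
every Hamming-1 pair transitively) is available for comparison.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class UniqueGroup:
    """A dereplicated sequence with its total and per-sample read counts."""

    seq: str
    count: int
    sample_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("group count must be >= 1")
        if self.sample_counts and sum(self.sample_counts.values()) != self.count:
            raise ValueError("sample counts do not sum to the total count")


@dataclass
class OTU:
    """A set of unique groups merged at <=1 nt difference."""

    otu_id: str
    members: list[UniqueGroup]
    representative: UniqueGroup
    total_count: int


@dataclass(frozen=True)
class ClusterParams:
    min_group_count: int = 3
    max_diff: int = 1  # fixed: single-nucleotide-difference merging
    merge_policy: str = "abundance_greedy"

    def __post_init__(self) -> None:
        if self.min_group_count < 1:
            raise ValueError("min_group_count must be >= 1")
        if self.max_diff != 1:
            raise ValueError("only single-nucleotide-difference merging is supported")
        if self.merge_policy not in ("abundance_greedy", "connected_components"):
            raise ValueError(f"unknown merge policy {self.merge_policy!r}")


def _check_equal_lengths(seqs: Sequence[str]) -> None:
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"sequences of mixed lengths {sorted(lengths)}")


def dereplicate(labelled_seqs: Iterable[tuple[str, str]]) -> list[UniqueGroup]:
    """Collapse ``(sequence, sample_id)`` observations at 100% identity.

    Returns one group per distinct sequence, sorted by descending count with
    lexicographic sequence tie-break; total counts are conserved.
    """
    per_seq: dict[str, Counter] = defaultdict(Counter)
    for seq, sample in labelled_seqs:
        per_seq[seq][sample] += 1
    _check_equal_lengths(list(per_seq))
    groups = [
        UniqueGroup(seq, sum(samples.values()), dict(samples))
        for seq, samples in per_seq.items()
    ]
    groups.sort(key=lambda g: (-g.count, g.seq))
    return groups


def abundance_filter(groups: Sequence[UniqueGroup], min_group_count: int = 3) -> list[UniqueGroup]:
    """Drop groups with fewer than ``min_group_count`` reads (order kept)."""
    return [g for g in groups if g.count >= min_group_count]


def hamming1_neighbors(groups: Sequence[UniqueGroup]) -> list[tuple[int, int]]:
    """Index pairs of groups at Hamming distance exactly 1.

    Uses masked-position hashing: two distinct equal-length sequences are at
    distance 1 iff they collide in the bucket of exactly one masked position,
    so the pair set is found in O(n * L) hashing work instead of an all-pairs
    scan.
    """
    seqs = [g.seq for g in groups]
    _check_equal_lengths(seqs)
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate sequences among groups; dereplicate first")
    if not groups:
        return []
    length = len(seqs[0])
    pairs: list[tuple[int, int]] = []
    for pos in range(length):
        buckets: dict[str, list[int]] = defaultdict(list)
        for idx, seq in enumerate(seqs):
            buckets[seq[:pos] + seq[pos + 1 :]].append(idx)
        for members in buckets.values():
            if len(members) > 1:
                # bucket-mates are unique sequences agreeing everywhere but pos
                pairs.extend(combinations(members, 2))
    return sorted(pairs)


def cluster(groups: Sequence[UniqueGroup], params: ClusterParams = ClusterParams()) -> list[OTU]:
    """Combine Hamming-1 neighbouring groups into OTUs.

    abundance_greedy (default): groups are visited in descending count
    (lexicographic tie-break); each joins the OTU of its highest-count
    already-assigned neighbour whose count >= its own, otherwise it founds a
    new OTU.  connected_components: OTUs are the connected components of the
    Hamming-1 graph.  Read counts are conserved either way.
    """
    below = [g for g in groups if g.count < params.min_group_count]
    if below:
        raise ValueError(
            f"{len(below)} groups below min_group_count={params.min_group_count}; "
            "apply abundance_filter first"
        )
    order = sorted(range(len(groups)), key=lambda i: (-groups[i].count, groups[i].seq))
    adjacency: dict[int, list[int]] = defaultdict(list)
    for i, j in hamming1_neighbors(groups):
        adjacency[i].append(j)
        adjacency[j].append(i)

    assignment: dict[int, int] = {}  # group index -> otu index
    n_otus = 0
    if params.merge_policy == "abundance_greedy":
        for idx in order:
            candidates = [
                j for j in adjacency[idx]
                if j in assignment and groups[j].count >= groups[idx].count
            ]
            if candidates:
                parent = min(candidates, key=lambda j: (-groups[j].count, groups[j].seq))
                assignment[idx] = assignment[parent]
            else:
                assignment[idx] = n_otus
                n_otus += 1
    else:  # connected_components
        for idx in order:
            if idx in assignment:
                continue
            stack = [idx]
            assignment[idx] = n_otus
            while stack:
                cur = stack.pop()
                for j in adjacency[cur]:
                    if j not in assignment:
                        assignment[j] = n_otus
                        stack.append(j)
            n_otus += 1

    members: dict[int, list[UniqueGroup]] = defaultdict(list)
    for idx in order:
        members[assignment[idx]].append(groups[idx])
    width = max(4, len(str(n_otus)))
    otus = []
    for otu_idx in range(n_otus):
        mem = members[otu_idx]
        otus.append(
            OTU(
                otu_id=f"otu{otu_idx + 1:0{width}d}",
                members=mem,
                representative=select_representative_members(mem),
                total_count=sum(g.count for g in mem),
            )
        )
    return otus


def select_representative_members(members: Sequence[UniqueGroup]) -> UniqueGroup:
    if not members:
        raise ValueError("empty OTU has no representative")
    return min(members, key=lambda g: (-g.count, g.seq))


def select_representative(otu: OTU) -> UniqueGroup:
    """The member with the largest read count (lexicographic tie-break)."""
    return select_representative_members(otu.members)


def otu_table(otus: Sequence[OTU]) -> pd.DataFrame:
    """OTU x sample read-count table; row sums equal OTU total counts."""
    samples = sorted({s for otu in otus for g in otu.members for s in g.sample_counts})
    data = {}
    for otu in otus:
        row = Counter()
        for g in otu.members:
            row.update(g.sample_counts)
        data[otu.otu_id] = [row.get(s, 0) for s in samples]
    table = pd.DataFrame.from_dict(data, orient="index", columns=samples, dtype=int)
    table.index.name = "otu_id"
    return table
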