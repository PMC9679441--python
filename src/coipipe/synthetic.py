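"""Synthetic fixtures: mock-community read pairs and Yule+coalescent trees.

The community generator emulates the 2-step tailed-PCR library layout of an
inline-tagged cox1 metabarcoding run: each forward read is
``tag + forward primer + insert 5' fragment`` and each reverse read is
``reverse primer + reverse-complemented insert 3' fragment``, with 2x300-style
read lengths, substitution errors, and Phred qualities tied to the error
draw.  The tree generator produces ultrametric gene trees with known species
membership: a Yule species tree whose tips are replaced by within-species
Kingman coalescent subtrees far shallower than the species divergences.

All outputs are deterministic given the spec's seed, and every generator
returns a ground-truth table so downstream precision/recall is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from coipipe.preprocess import IUPAC_SETS, PrimerPair, reverse_complement
from coipipe.seqio import ReadPair, SampleManifest, SequenceRecord, write_fastq

#: Inline index tags of the eight Takamigawa River sequencing runs.
STUDY_TAGS = (
    ("DRR311861", "TCGACTAG"),
    ("DRR311862", "TTCTAGCT"),
    ("DRR311863", "CCTAGAGT"),
    ("DRR311864", "GCGTAAGA"),
    ("DRR311865", "CTATTAAG"),
    ("DRR311866", "AAGGCTAT"),
    ("DRR311867", "GAGCCTTA"),
    ("DRR311868", "TTATGCGA"),
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CommunitySpec:
    """Mock-community parameters.

    Defaults mirror the target assay: 313-nt haplotypes sequenced as 2x300
    reads behind 8-nt inline tags and the degenerate cox1 primer pair, with
    log-normally skewed haplotype abundances and a low per-base substitution
    error rate typical of merged MiSeq amplicon data.
    """

    n_haplotypes: int = 6
    haplotype_length: int = 313
    min_pairwise_distance: int = 5
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.0
    per_base_error_rate: float = 0.002
    n_read_pairs: int = 800
    read_length: int = 300
    primers: PrimerPair = field(default_factory=PrimerPair)
    tags: tuple[tuple[str, str], ...] = STUDY_TAGS
    linker: str = ""
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_pairwise_distance < 2:
            raise ValueError("min_pairwise_distance must be >= 2")
        if not 0.0 <= self.per_base_error_rate <= 1.0:
            raise ValueError("per_base_error_rate must lie in [0, 1]")
        if self.n_haplotypes < 1 or self.n_read_pairs < 0:
            raise ValueError("counts must be positive")

    @property
    def manifest(self) -> SampleManifest:
        return SampleManifest(self.tags)


@dataclass
class CommunityData:
    """Generated reads plus exact ground truth."""

    fwd_reads: list[SequenceRecord]
    rev_reads: list[SequenceRecord]
    truth: pd.DataFrame  # read_id, haplotype_id, sample_id, n_errors
    haplotypes: dict[str, str]

    def pairs(self) -> list[ReadPair]:
        return [ReadPair(f, r) for f, r in zip(self.fwd_reads, self.rev_reads)]

    def write(self, outdir: str | Path, prefix: str = "community") -> tuple[Path, Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        p_fwd = outdir / f"{prefix}_R1.fastq"
        p_rev = outdir / f"{prefix}_R2.fastq"
        p_truth = outdir / f"{prefix}_truth.tsv"
        write_fastq(self.fwd_reads, p_fwd)
        write_fastq(self.rev_reads, p_rev)
        self.truth.to_csv(p_truth, sep="\t", index=False)
        return p_fwd, p_rev, p_truth


def _random_haplotypes(rng: np.random.Generator, spec: CommunitySpec,
                       max_retries: int = 1000) -> list[str]:
    haps: list[np.ndarray] = []
    tries = 0
    while len(haps) < spec.n_haplotypes:
        cand = rng.choice(_BASES, size=spec.haplotype_length)
        if all(int((cand != h).sum()) >= spec.min_pairwise_distance for h in haps):
            haps.append(cand)
        else:
            tries += 1
            if tries > max_retries:
                raise RuntimeError(
                    "cannot satisfy min_pairwise_distance after "
                    f"{max_retries} retries"
                )
    return [h.tobytes().decode() for h in haps]


def _resolve_degenerate(rng: np.random.Generator, primer: str) -> str:
    return "".join(
        b if len(IUPAC_SETS[b]) == 1 else sorted(IUPAC_SETS[b])[rng.integers(len(IUPAC_SETS[b]))]
        for b in primer
    )


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, tuple[int, ...], int]:
    """Substitute bases at ``rate``; qualities: error bases Phred 3-15,
    correct bases Phred 30-40 (so the Q20 filter is exercisable)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    is_err = rng.random(len(arr)) < rate
    n_err = int(is_err.sum())
    if n_err:
        for pos in np.flatnonzero(is_err):
            alternatives = _BASES[_BASES != arr[pos]]
            arr[pos] = alternatives[rng.integers(3)]
    qual = rng.integers(30, 41, size=len(arr))
    if n_err:
        qual[is_err] = rng.integers(3, 16, size=n_err)
    return arr.tobytes().decode(), tuple(int(q) for q in qual), n_err


def generate_community(spec: CommunitySpec) -> CommunityData:
    """Simulate tagged paired reads from a skewed mock community."""
    rng = np.random.default_rng(spec.seed)
    haps = _random_haplotypes(rng, spec)
    hap_ids = [f"hap{i + 1:03d}" for i in range(spec.n_haplotypes)]

    weights = rng.lognormal(spec.abundance_mu, spec.abundance_sigma, spec.n_haplotypes)
    probs = weights / weights.sum()
    hap_choice = rng.choice(spec.n_haplotypes, size=spec.n_read_pairs, p=probs)
    samples = [s for s, _ in spec.tags]
    sample_choice = rng.integers(len(samples), size=spec.n_read_pairs)
    tag_by_sample = dict(spec.tags)

    fwd_reads, rev_reads, rows = [], [], []
    for i in range(spec.n_read_pairs):
        hap_idx = int(hap_choice[i])
        sample = samples[int(sample_choice[i])]
        insert = haps[hap_idx]
        fwd_primer = _resolve_degenerate(rng, spec.primers.fwd)
        rev_primer = _resolve_degenerate(rng, spec.primers.rev)

        head = tag_by_sample[sample] + spec.linker + fwd_primer
        fwd_template = (head + insert)[: spec.read_length]
        rev_template = (rev_primer + reverse_complement(insert))[: spec.read_length]

        read_id = f"read{i + 1:06d}"
        fseq, fqual, ferr = _apply_errors(rng, fwd_template, spec.per_base_error_rate)
        rseq, rqual, rerr = _apply_errors(rng, rev_template, spec.per_base_error_rate)
        fwd_reads.append(SequenceRecord(f"{read_id}/1", fseq, fqual))
        rev_reads.append(SequenceRecord(f"{read_id}/2", rseq, rqual))
        rows.append(
            {
                "read_id": read_id,
                "haplotype_id": hap_ids[hap_idx],
                "sample_id": sample,
                "n_errors": ferr + rerr,
            }
        )
    truth = pd.DataFrame(rows, columns=["read_id", "haplotype_id", "sample_id", "n_errors"])
    return CommunityData(fwd_reads, rev_reads, truth, dict(zip(hap_ids, haps)))


# ---------------------------------------------------------------------------
# Yule-over-coalescent trees with known species membership
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of the simulated gene tree.

    A Yule species tree with ``n_species`` tips is generated at
    ``speciation_rate``; each species tip is replaced by a Kingman coalescent
    over ``tips_per_species`` lineages whose pairwise rate is scaled so the
    expected within-species depth is the shallowest species divergence
    divided by ``depth_ratio``.  With one species, the tree is a plain
    coalescent at ``within_species_coalescent_rate``.
    """

    n_species: int = 5
    tips_per_species: int = 6
    speciation_rate: float = 1.0
    within_species_coalescent_rate: float = 1.0
    depth_ratio: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.tips_per_species < 1:
            raise ValueError("n_species and tips_per_species must be >= 1")
        if min(self.speciation_rate, self.within_species_coalescent_rate,
               self.depth_ratio) <= 0:
            raise ValueError("rates and depth_ratio must be positive")


class _Node:
    __slots__ = ("height", "children", "label")

    def __init__(self, height: float, children: list | None = None, label: str | None = None):
        self.height = height
        self.children = children or []
        self.label = label

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(
            f"{c._nwk()}:{self.height - c.height:.12f}" for c in self.children
        )
        return f"({inner})"


def _coalescent(rng: np.random.Generator, labels: list[str], pair_rate: float) -> _Node:
    nodes = [_Node(0.0, label=lb) for lb in labels]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * (k - 1) / 2.0 * pair_rate))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        merged = _Node(t, [nodes[i], nodes[j]])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0]


def _yule_backward(rng: np.random.Generator, n: int, rate: float) -> _Node:
    """Reconstructed pure-birth tree: backward from n tips, the waiting time
    to the next deeper speciation with k lineages is Exp(k * rate)."""
    nodes = [_Node(0.0, label=f"S{i}") for i in range(n)]
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(1.0 / (k * rate))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        merged = _Node(t, [nodes[i], nodes[j]])
        nodes = [n_ for idx, n_ in enumerate(nodes) if idx not in (i, j)] + [merged]
    return nodes[0]


def _rescale(node: _Node, factor: float) -> None:
    node.height *= factor
    for c in node.children:
        _rescale(c, factor)


def generate_tree(spec: TreeSpec) -> tuple[str, pd.DataFrame]:
    """Simulate an ultrametric gene tree; returns (newick, membership table).

    The membership table maps each tip label to its true species id.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    def species_labels(s: int) -> list[str]:
        labels = [f"sp{s + 1:02d}_t{j + 1:02d}" for j in range(spec.tips_per_species)]
        rows.extend({"tip": lb, "species": f"sp{s + 1:02d}"} for lb in labels)
        return labels

    if spec.n_species == 1:
        root = _coalescent(rng, species_labels(0), spec.within_species_coalescent_rate)
    else:
        sp_tree = _yule_backward(rng, spec.n_species, spec.speciation_rate)
        # attachment height of each species tip = its parent's height
        attach: dict[str, float] = {}

        def walk(node: _Node, parent_height: float | None) -> None:
            if not node.children:
                attach[node.label] = parent_height if parent_height is not None else node.height
            for c in node.children:
                walk(c, node.height)

        walk(sp_tree, None)
        min_divergence = min(attach.values())
        target_depth = min_divergence / spec.depth_ratio
        m = spec.tips_per_species

        def subtree_for(s: int, limit: float) -> _Node:
            labels = species_labels(s)
            if m == 1:
                return _Node(0.0, label=labels[0])
            pair_rate = 2.0 * (1.0 - 1.0 / m) / target_depth
            sub = _coalescent(rng, labels, pair_rate)
            for _ in range(100):
                if sub.height < limit:
                    return sub
                sub = _coalescent(rng, labels, pair_rate)
            _rescale(sub, 0.9 * limit / sub.height)  # pathological draw: clamp
            return sub

        s_counter = [0]

        def replace_tips(node: _Node) -> _Node:
            if not node.children:
                s = s_counter[0]
                s_counter[0] += 1
                return subtree_for(s, attach[node.label])
            node.children = [replace_tips(c) for c in node.children]
            return node

        root = replace_tips(sp_tree)

    membership = pd.DataFrame(rows, columns=["tip", "species"])
    return root.newick(), membership
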