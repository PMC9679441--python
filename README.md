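# coipipe

A toolkit for COI (cox1) amplicon metabarcoding of bulk community samples —
the kind of survey where hundreds of small aquatic invertebrates are
collected in one net, sequenced together on a 2×300 paired-end run, and
resolved into species afterwards.  It implements the full downstream
workflow for the 313 bp Leray fragment:

1. **Demultiplexing** of inline 8-nt index tags from a 2-step tailed-PCR
   library layout, with exact tag matching on the forward read.
2. **Preprocessing**: Phred-quality filtering (default: discard a pair when
   either mate's mean quality < 20), IUPAC-aware degenerate primer trimming,
   ungapped read-pair merging with higher-quality-base consensus, and
   selection of amplicons at exactly the 313 bp target length.
3. **OTU clustering by abundance-aware single-mismatch merging**: merged
   amplicons are dereplicated at 100% identity into unique groups with read
   counts; groups with fewer than 3 reads are discarded; groups at Hamming
   distance 1 are then combined into OTUs by walking groups in decreasing
   abundance and attaching each to its most abundant already-assigned
   neighbour with count at least its own.  Low-count sequencing-error
   variants are absorbed by their parent haplotypes while genuine
   co-occurring haplotypes survive as separate OTUs.  The most abundant
   member of each OTU is its representative.
4. **GMYC species delimitation**: on an ultrametric tree of OTU
   representatives, the single-threshold Generalised Mixed Yule Coalescent
   model finds the time T separating between-species (Yule-like)
   branching from within-species coalescence.  Writing the branching
   events at heights h_1 ≤ … ≤ h_(n−1) with waiting times x_i, the rate in
   interval i is

       r_i = λ_div·k_i^p_div + λ_coal·Σ_j (m_ij(m_ij−1))^p_coal

   with k_i the between-species lineage count and m_ij the lineage count
   of within-species cluster j, and log L = Σ_i [log r_event(i) − r_i·x_i]
   where r_event(i) is the rate of the process class that produced event i.
   The fitted threshold partitions the tips into GMYC species (clusters
   plus singletons); a χ² likelihood-ratio test compares against a
   single-process null.
5. **Taxonomy assignment** from BLAST-style tabular best-hit files:
   percent identity = 100 × identical sites / query size, rounded
   half-away-from-zero to one decimal, with species-level assignment
   requiring identity strictly greater than 95%.

A `synthetic` module simulates tagged mock-community read pairs and
Yule-over-coalescent gene trees with known ground truth, so every stage is
testable at desk scale without downloading sequencing runs.

The package ships one real dataset: `coipipe.taxonomy.bundled_hits_table()`
returns the best INSD matches for the 369 GMYC species delimited in a
riverine cox1 survey of the Takamigawa River (Nara, Japan), transcribed
from the published table of similarity scores.

## Worked example

Simulate a gene tree with 5 species × 6 tips whose species divergences are
50× deeper than within-species coalescence, then delimit:

```
$ coipipe simulate tree --out tree.nwk --seed 12
$ coipipe gmyc --tree tree.nwk --outdir gmyc_out
T=0.100873  n_species=5  LR=19.769  p=0.0002
```

The fitted threshold (0.10 time units) cuts the tree into exactly the five
simulated species; the likelihood-ratio statistic 19.8 on 3 degrees of
freedom rejects the one-species null (p = 0.0002).
`gmyc_out/gmyc_entities.tsv` maps every tip to its species cluster.

Assign taxonomy on the bundled survey table:

```
$ coipipe assign --hits <path to takamigawa_insd_best_hits.tsv> --out assigned.tsv
species=137  unassigned=232
```

Of the 369 queried species representatives, 137 exceed the strict 95%
identity threshold and are accepted as species-level identifications.

Run the whole read-processing pipeline on a simulated mock community
(6 haplotypes, 400 read pairs, 0.2% per-base error):

```
$ coipipe simulate community --outdir sim --seed 7 --n-read-pairs 400
$ coipipe run --fwd sim/community_R1.fastq --rev sim/community_R2.fastq \
      --manifest manifest.tsv --outdir out
total_reads	400
demultiplexed	392
...
unique_groups	60
groups_after_abundance_filter	6
otus	6
```

The funnel shows 8 reads lost to tag errors, 60 unique sequences collapsing
to the 6 true haplotypes after the <3-read filter, and one OTU per
haplotype — each representative identical to a true haplotype.

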