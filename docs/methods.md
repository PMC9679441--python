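# Methods

## Scope and data model

The package models the downstream half of a COI metabarcoding experiment:
it consumes demultiplexable paired FASTQ, an ultrametric Newick tree of OTU
representatives, and BLAST-style tabular best-hit files.  It does not infer
trees (the delimitation module treats the tree as data) and does not run
BLAST; both steps depend on external resources (MCMC tree inference,
INSD contents) that cannot be frozen inside a reproducible toolkit.

## Read preprocessing

Reads carry an inline 8-nt tag at the 5' end of the forward mate.  Tags are
matched exactly, on the forward read only: the library design puts a single
tag per run and tolerating mismatches would trade a known small loss of
reads (~2% at typical error rates, measurable in the simulator) for a risk
of cross-sample bleed.

"Quality below 20" is interpreted, by default, as mean Phred of either mate
below 20.  Because published pipelines vary, `FilterConfig.quality_policy`
also offers `min` (any base below threshold) and `window` (mean over any
25-base sliding window below threshold).  The default target length is
exactly 313 nt — a fixed-length amplicon makes 100%-identity dereplication
and Hamming-distance clustering well-defined — and amplicons containing N
are dropped for the same reason.

Primer trimming is IUPAC-aware with ≤2 mismatches by default (degenerate
metazoan COI primers are expected to mismatch some templates); a
configurable leading window accommodates layouts that retain linker bases.
Pairs are trimmed first (each mate's 5' primer) and merged second.  Merging
considers every ungapped overlap of at least 20 nt, scores each by match
count (largest overlap breaks ties), and rejects merges whose best overlap
has a mismatch fraction above 0.1.  In the overlap the base with the higher
Phred score wins; the consensus quality is the maximum of the two.
Substitution-only merging is deliberate: indel errors produce off-length
amplicons that the 313 bp selection removes anyway.

## OTU clustering

Unique sequences are found by exact hashing; groups below 3 reads are
discarded; Hamming-1 neighbour pairs are found by masked-position hashing
(two distinct equal-length sequences are at distance 1 iff they collide in
the bucket of exactly one masked position), which is O(n·L) instead of the
O(n²·L) all-pairs scan.

The default merge policy (`abundance_greedy`) visits groups in decreasing
read count (ties broken lexicographically by sequence) and attaches each
group to the OTU of its most abundant already-assigned neighbour whose
count is at least its own; a group with no such neighbour founds an OTU.
This mirrors the rationale of comparing read abundances between
neighbouring sequences: a distance-1 variant that is rarer than its
neighbour is most plausibly a sequencing/PCR error of it.  The alternative
`connected_components` policy merges every Hamming-1 pair transitively.
The greedy partition always refines the component partition; both conserve
read counts, and tests enforce both facts.  All orderings are
deterministic, so repeated runs are byte-identical.

## GMYC delimitation

The single-threshold generalised mixed Yule coalescent model is fitted to
an ultrametric tree.  Events older than threshold T follow a generalised
Yule process with rate λ_div·k^p_div in the number k of between-species
lineages; events younger than T are coalescences within the clusters
obtained by cutting every branch at T, with class rate
λ_coal·Σ_j (m_j(m_j−1))^p_coal over clusters j holding m_j ≥ 2 lineages.
Below the threshold, the k species lineages persist without diversifying
and contribute their exposure to the Yule term.  Each interval between
branching events contributes −r·x (total rate times waiting time) and each
event contributes the log of the rate of its process class — the class
rate, not the single cluster's own rate.  That choice matters: charging
each coalescent event only its own cluster's rate makes the likelihood the
density of the waiting times *plus* a per-cluster event labelling, and the
labelling entropy systematically depresses the mixed model relative to the
unlabelled one-process null; with class rates the mixed model dominates
the null whenever the tree is genuinely structured.  At T = 0 the model
collapses to a pure generalised Yule likelihood and at T ≥ root height to
the null form — both identities are tested to 1e-9.

The exponents generalise the linear Yule (p = 1 in k) and Kingman
(p = 1 in m(m−1)) rate laws and are searched in [0, 2].  The likelihood
separates into a diversification part and a coalescent part, and each rate
has a closed-form conditional maximum (events / exposure), so fitting a
candidate threshold reduces to two bounded one-dimensional profile
searches over the exponents (41-point grid, then bounded scalar
refinement).  This is deterministic and needs no random starts.

The likelihood is piecewise constant in T between branching times, so
candidate thresholds are midpoints between consecutive distinct branching
times, plus one just below the shallowest event (all tips singletons) and
one at the root (one species — exactly the null, which also guarantees
logL_gmyc ≥ logL_null).  Ties are resolved towards the larger threshold
(fewer species).  The LR statistic 2·(logL_gmyc − logL_null) is referred to
a χ² distribution with 3 degrees of freedom by default (threshold plus the
extra rate class); published usage varies, so `df` is configurable.
Tied branching heights produce zero-length intervals whose exposure terms
vanish; event rates stay positive, so no special merging is needed.

Ultrametricity is validated on input: any tip whose root-to-tip distance
falls more than a relative tolerance (default 1e-6) short of the maximum is
reported.  Newick parsing preserves underscores in tip labels.

## Taxonomy assignment

Percent identity is 100·identical/size rounded half-away-from-zero to one
decimal; this convention reproduces conventional reported similarity
scores exactly (e.g. 296/311 → 95.2).  Species-level assignment requires
identity strictly above 95.0; the behaviour at exactly 95.0 is a contract
of this package (no reference case decides it).  Coarser ranks
(genus/family/order) are configurable thresholds with no defaults, since
critical values differ between marker sets and reference papers.  The
bundled Takamigawa survey table carries the printed similarity score in a
`printed_identity` column so the rounding convention is testable against
369 independent published values.

## Synthetic data

The community generator emulates what the pipeline consumes, not the
sequencer: reads are `tag + degenerate-primer realisation + insert
fragment` (forward) and `reverse primer + reverse-complemented insert
fragment` (reverse), at 300 nt, with i.i.d. substitution errors and
qualities tied to the error draw (error bases Phred 3–15, correct bases
30–40).  Defaults — 6 haplotypes of 313 nt at pairwise distance ≥ 5,
log-normal(0, 1) abundances, 800 read pairs over the 8 inline tags used in
the Takamigawa runs, 0.2% per-base error — give every haplotype enough
reads to clear the 3-read filter while producing a realistic halo of
distance-1 error groups.  Not modelled: indels, chimeras, quality-by-cycle
MiSeq error profiles, and PCR abundance bias; passing tests therefore
demonstrate correctness of the algorithms under substitution noise, not
robustness to every artefact of real libraries.

The tree generator builds a Yule species tree (backward construction:
with k lineages the next deeper speciation is exponential with rate k·λ),
then replaces each species tip by a Kingman coalescent over its tips whose
pairwise rate is scaled so the expected within-species depth equals the
shallowest species divergence divided by `depth_ratio` (default 50).  A
coalescent draw deeper than the species' attachment point is redrawn (up
to 100 times, then rescaled to fit — practically unreachable at the
default ratio).  Trees are ultrametric by construction and deterministic
given the seed.

## Problem sizes in tests

The test suite runs the stochastic checks at the sizes that make them
meaningful yet quick: 100 simulated communities of 800 read pairs for
denoising recovery, 100 random clustering instances of up to 500 groups
against a brute-force graph oracle, 100 trees of 30 tips for GMYC recovery
plus 100 one-species trees of 20 tips for null calibration, and 20-replicate
parameter recovery on 200-tip trees (coalescent rate within 25% median
relative error, exponents fixed at their generating value — with exponents
free, rate and exponent trade off and the rate alone is not identifiable
to that precision at these sizes).  `scripts/acceptance.py` re-runs the
same measurements at 50 seeds per quantity.

## Known limitations

- The OTU merge rule is one reasonable formalisation of abundance-aware
  single-mismatch merging; border cases (equal-count neighbours, chains
  through low-count intermediates) follow the documented tie-breaks rather
  than any external reference implementation.
- Single-threshold GMYC only; multiple-threshold variants and Bayesian
  delimitation (bGMYC, PTP) are out of scope.
- The χ²(3) reference for the LR test is an approximation; on simulated
  one-species trees it is conservative (rejection rate ≈ 2% at α = 0.05).
- Taxonomy assignment is per-best-hit; no lowest-common-ancestor logic.
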