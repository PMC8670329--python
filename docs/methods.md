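# Methods

## The problem and the model

Bulk TCR sequencing of an antigen-stimulated culture yields tens of
thousands of clonotypes, almost all irrelevant to the stimulating antigen.
`cetfinder` identifies *clusters of expanded TCRs* (CETs): groups of
homologous, frequent clonotypes whose joint size and abundance are
improbable under random V(D)J recombination. The logic exploits the fact
that an epitope-specific response typically comprises multiple clonotypes
with convergent CDR sequence features, so homology plus expansion is a far
stronger signal than frequency alone.

The analysis unit is the *shortlist*: the `shortlist_n` (default 1000) most
frequent clonotypes of one chain in one sample, each keyed by
(V call, J call, CDR3 nucleotide sequence). Rows sharing a key are merged
(summed counts) before anything else, non-productive junctions are dropped,
and frequencies are recomputed per sample over the retained clonotypes.
Shortlist members keep their sample-level frequencies; they are not
renormalised to the shortlist (configurable, but renormalisation would
inflate every cluster's abundance by the same factor and cancel in the
null comparison anyway, since trials carry the same multiset).

## Distance metric

The v1 TCRdist metric scores the four loops most likely to contact
peptide:MHC — CDR1, CDR2, CDR2.5 (all germline-determined by the V gene)
and the CDR3 (the IMGT junction trimmed of 3 N-terminal / 2 C-terminal
anchor residues). Per aligned position the cost is
`min(cap, max(0, cap − BLOSUM62(a,b)))` with `cap = 4`; unequal-length
loops are aligned by inserting one contiguous gap block into the shorter
loop at the cost-minimising position (leftmost on ties), each gap position
costing 4. Loop costs are summed with the CDR3 triple-weighted. All
constants live in `TcrdistParams` and are configurable; the defaults
follow the published v1 definition, which the source study names but does
not restate, so byte-level concordance with the authors' own code would
need validation against that code rather than against anything here.
Distances are integers throughout — no floating point enters the kernel —
which makes the numba batch kernel exactly equal to the scalar reference
implementation, a property the tests assert rather than assume.

Allele suffixes (`*01`) are stripped to gene level for germline loop
lookup, since the three germline loops are gene-determined at the
resolution the metric needs; full calls are preserved in output.

## Clustering and the threshold ladder

Agglomerative clustering (complete linkage by default; average and single
available) is cut at the fixed ladder 0, 5, …, 50. The linkage method is
not dictated by the source material; complete linkage is the default here
because it bounds within-cluster diameter, which matches the
homology-cluster reading, and the choice is configurable. Cuts are
height-inclusive (`≤ t`), so threshold 0 groups exactly the clonotypes
with identical CDR profiles. Determinism is guaranteed by labelling
clusters with their smallest member index and merging the
lexicographically smallest label pair on equal heights.

Because complete/average/single linkage are monotone (merge heights never
decrease), the sweep needs only merges up to the ladder maximum, and an
item whose every pairwise distance exceeds the maximum can never join any
cluster at any cut: for all three linkages the cluster-to-cluster distance
is bounded below by the minimum pairwise distance between their members.
The sweep therefore pre-prunes such items and agglomerates only the
remainder — identical partitions, an order of magnitude faster on random
repertoires where >99% of pairs are far apart. A test verifies the pruned
sweep against cuts of the full dendrogram.

## The recombination null and empirical significance

Each junction is decomposed into 14 recombination elements (germline
V/D/J calls, trim counts, P segments, non-templated inserts; α chains use
the single V–J insert and leave D slots empty). Random TCRs resample each
element *independently* from its background pool — interpreting the
permutation of elements column-wise rather than as whole-row permutation,
which would merely reproduce real TCRs — destroying V–junction–J linkage
while preserving marginal element usage. Non-productive assemblies
(out-of-frame, stop codon, missing leading cysteine) are rejected and
redrawn (cap 1000 attempts per TCR). A without-replacement per-slot
permutation mode is available behind `null_mode="permutation"`; with the
default background sizes the two modes are statistically indistinguishable
in our tests.

A trial is `n` such TCRs carrying exactly the observed shortlist's
frequency multiset, assigned by a uniformly random permutation (any
rank-preserving assignment would couple frequency to generation order,
which is meaningless for random TCRs). Trials are clustered identically to
the observed data and reduced to per-threshold (size, geometric-mean
frequency) pairs.

An observed cluster's p-value is the fraction of trials containing, at the
same threshold, a cluster whose size is at least the observed size
(dominance mode, default) — or exactly equal (`exact_size`) — with
geometric mean frequency at least as high. Dominance is the default
because it is monotone and conservative: a larger, equally frequent random
cluster is at least as surprising. Significance is `p < alpha` (default
0.01, i.e. fewer than 10 exceedances in 1000 trials; the boundary is
exact and tested). No multiple-testing correction is applied across
thresholds or clusters — a deliberately liberal choice mirroring the
per-cluster rule of the source procedure; redundancy across thresholds is
collapsed downstream by master-list aggregation, and the empirical
random-control check (below) shows the practical false-positive rate is
near zero because each trial's *best* cluster is what competes with each
observed cluster.

Trial clusterings depend only on the generated TCRs, not on the assigned
frequencies, so callers analysing several samples with the same background
and shortlist multiset may reuse trials via `run_sample(..., trials=)`.

## Aggregation, enrichment, deep queries

Members of significant CETs from all thresholds (and samples) are combined
into a deduplicated master list with provenance and reclustered at the
ladder maximum for final reporting (conserving membership; final ids
ordered by size then abundance). Cross-condition enrichment of a CET is
the geometric mean over members of `freq_condition / max(freq_ref, floor)`
with `floor = 1 / (total reference reads)` — the reference sample's
detection limit; the source text does not state its handling of
reference-undetected clonotypes, so the floor rule is this package's
decision (configurable, as is an arithmetic-mean option). The display
filter keeps CETs with ≥ 3 members and ≥ 100× enrichment in any
condition. Deep-repertoire queries match on the full nucleotide-level
clonotype key; a frequency is only ever reported verbatim from the deep
table. Text consensus strings take the modal residue per column over the
CET's dominant CDR3 length, with `x` where no residue reaches 50%.

## Synthetic data: what it emulates and what it does not

`make_background` assembles productive clonotypes from a bundled
*synthetic* mini germline reference (human-style gene names; generated
loop and nucleotide content — real analyses must supply an IMGT-derived
table) with Zipf-skewed V/J usage, random inserts/trims giving a junction
length distribution centred near 15 aa, and clone sizes from a discrete
power law with exponent 2 truncated at 1 read (configurable) — the
heavy-tailed structure real shortlists show. `spike_families` plants
homologous expanded families: members share V/J and vary only at a fixed
set of `cdr3_divergence` trimmed-CDR3 positions, so within-family pairwise
TCRdist is bounded by `divergence × cap × cdr3_weight` by construction;
member counts are `expansion_fold ×` the median background count.
`make_condition_pair` emulates matched cultures by independent multinomial
resampling at depth `2n` (plus the spikes in the antigen-positive arm),
which reproduces the observation that most low-frequency clonotypes are
unique to one culture (>50% turnover with the defaults).

Not emulated: thymic selection, α:β pairing, sequencing error, primer
bias, or real germline sequence content. Passing tests therefore
demonstrate the statistical machinery — calibration of the null, recovery
of planted signal, kernel exactness — not performance on any real
repertoire.

## Problem sizes and numerical choices

The test suite and the acceptance script run the pipeline at shortlists of
500–1000 clonotypes with 200 null trials and a 2000-clonotype latent
background for condition pairs; these sizes give stable results for the
calibration and recovery checks while keeping runs to minutes. The
published default (`n_trials=1000`) is the configured production value.
Geometric means are computed in log space; zero or negative frequencies
are rejected loudly. Empirical p-values are reported exactly as
`n_exceed / n_trials` (0 rendered as `<1/n_trials` in display output).
Duplicate clonotype keys are forbidden in parsed samples (the reader
merges them) but tolerated inside null trials, where independent draws may
collide — a degenerate single-TCR background legitimately collapses every
trial to one cluster.

## Known limitations

* The bundled germline reference is synthetic; results on real data
  require a real CDR/nucleotide table and inherit its accuracy.
* Unpaired single-chain analysis cannot distinguish two TCRs sharing one
  chain; deep-repertoire matching is correspondingly more specific for β
  than α chains.
* The raw `p < alpha` rule is liberal across the ladder by design; users
  wanting family-wise control should lower `alpha`.
* Element pools inherit any artefacts of the background repertoire used to
  build them; small pools reduce null diversity and can make the test
  conservative.
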