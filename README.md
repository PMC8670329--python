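# cetfinder

Identify **Clusters of Expanded TCRs (CETs)** — groups of homologous,
antigen-expanded T-cell receptor clonotypes — inside bulk-sequenced immune
repertoires, without cell sorting or tetramer labelling.

## Who this is for

Immunologists and computational biologists who have clonotype tables from
bulk TCR sequencing of antigen-stimulated cultures (AIRR Rearrangement
TSVs, aligner clonotype exports, or genomic-DNA TCRβ exports) and want to
know which clonotypes expanded *because of the antigen*. Epitope-specific
responses typically comprise several clonotypes with convergent CDR
sequences; `cetfinder` exploits that convergence: a cluster of similar,
frequent receptors is far stronger evidence of antigen-driven expansion
than the frequency of any single clonotype.

## The method

For one chain of one sample:

1. **Shortlist** the *n* = 1000 most frequent clonotypes, each keyed by
   (V segment, J segment, CDR3 nucleotide sequence).
2. **TCRdist**: compute all ≈ n²∕2 pairwise distances. For each of the four
   CDR loops (CDR1, CDR2, CDR2.5 from the V germline; CDR3 from the trimmed
   junction) the per-position cost is `min(4, 4 − BLOSUM62(a,b))` clamped at
   0, gaps cost 4 per position, and loop costs are summed with the CDR3
   triple-weighted — an integer distance, 0 for identical CDR sequences and
   typically >100 for unrelated receptors.
3. **Cluster** the distance matrix (agglomerative, complete linkage) and cut
   at thresholds 0, 5, 10, …, 50. Each cluster is parameterised by its
   member count *m* and the geometric mean frequency ḡ of its members.
4. **Null model**: random TCRs are built by independently resampling the 14
   V(D)J recombination elements (V/D/J calls, trims, P segments,
   non-templated inserts) from a large background repertoire and reassembling
   productive junctions. Each of *T* = 1000 trials carries exactly the
   observed shortlist's frequency multiset and is clustered identically.
5. **Significance**: a cluster's empirical p-value is the fraction of trials
   containing, at the same threshold, a cluster with ≥ *m* members and
   geometric mean frequency ≥ ḡ. CETs are called at p < 0.01 (fewer than 10
   exceedances in 1000 trials).
6. **Aggregate**: members of significant CETs from all thresholds (and
   samples) are merged into a master list, reclustered at threshold 50, and
   screened for ≥ 100× average fold enrichment versus the antigen-negative
   condition; CET members can be matched against deep uncultured
   repertoires at nucleotide-level identity.

See `docs/methods.md` for assumptions, parameter meanings and limitations.
The bundled germline reference is a synthetic stand-in used by the
simulator and tests; analyses of real data must supply an IMGT-derived
CDR/nucleotide table (`--germline`, `--germline-nt`).

## Worked example

Simulate a matched antigen-negative / antigen-positive culture pair with
three spiked homologous families (five members each, ≤2 CDR3 substitutions,
150× expanded), then run the full pipeline:

```bash
cetfinder simulate --n 2000 --seed 11 --spike-families 3 --members 5 \
    --divergence 2 --expansion-fold 150 --out-dir sim
cetfinder run --input sim/ag_plus.tsv --background sim/background.tsv \
    --condition Ag+ --shortlist-n 500 --trials 200 --seed 11 --out-dir out
```

which prints

```
361 clusters scored, 23 significant; wrote out/ag_plus_significant_cets.tsv
```

361 cluster/threshold combinations had ≥2 members; 23 beat the null at
p < 0.01 — these are the spiked families, recovered at several thresholds
each (each row of the output TSV is one member clonotype with its CET id,
threshold, cluster size, geometric mean frequency and p-value; p-value 0.0
means no exceedance in 200 trials, i.e. p < 0.005). Comparing conditions:

```bash
cetfinder compare --input sim/ag_minus.tsv --condition Ag- \
    --input sim/ag_plus.tsv --condition Ag+ \
    --background sim/background.tsv --reference Ag- \
    --shortlist-n 500 --trials 200 --seed 11 --out-dir cmp
```

```
3 final CETs (3 enriched >= 100x); wrote cmp/final_cets.tsv
```

The three spiked families emerge as the three final CETs after master-list
reclustering at threshold 50, every one flagged as ≥100× enriched in the
Ag+ condition (the per-member frequencies and per-CET folds are in
`cmp/condition_matrix.tsv`). Querying the final CETs back against the deep
Ag+ table matches every member at nucleotide identity:

```bash
cetfinder query --cets cmp/final_cets.tsv --deep sim/ag_plus.tsv --out-dir q
# 15/15 members matched; wrote q/deep_matches.tsv
```

Every command writes a JSON manifest (config snapshot, input digests,
seed, timings) alongside its outputs.

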