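# Methods

## Problem and model

`seqtu` treats bacterial TU inference as binary classification of
*junctions*: for each pair of consecutive genes on the same strand, decide
from the strand-specific per-base coverage (RAPSN) whether the pair is
co-transcribed under the profiled condition. Positive junctions are then
chained: every maximal run of genes connected by positive junctions is one
TU, every unconnected gene a single-gene TU, so each prediction partitions
the annotated genes. Overlapping TUs are out of scope.

The biological premise is that a transcribed TU produces one RNA molecule,
so coverage should be continuous across its internal intergenic regions
and of comparable level across its genes; defective or truncated
transcripts are assumed to be degraded quickly enough not to blur this
signal. Technical noise still causes fluctuations, which is why the
decision is learned rather than thresholded.

## Coordinates and inputs

All coordinates are 0-based half-open internally; GFF3/GenBank 1-based
inclusive coordinates are converted at the I/O boundary. Only features of
a configurable type (default `gene`) are read. Annotations spanning
multiple contigs are rejected with instructions to split the input and
process replicons independently. Coverage can be built from SAM/BAM
(aligned blocks only, so N/D CIGAR gaps contribute nothing), BED6 read
intervals, or per-strand bedGraph. All alignment records present in the
input are used; any multi-mapper or quality filtering is left to upstream
tools. Paired-end data contribute per-read coverage to RAPSN; the full
first-mate-start to second-mate-end fragment span is used only as spanning
evidence.

## Features

Six statistics per candidate (left flank, intergenic region IR, right
flank):

| feature | definition | default-relevant constants |
|---|---|---|
| `gap_count` | IR positions with RAPSN = 0 | — |
| `gap_fraction` | `gap_count / |IR|` (0 for zero-length IR) | — |
| `log2_fc_left_ir`, `log2_fc_right_ir`, `log2_fc_left_right` | `log2((mean_a + 1)/(mean_b + 1))` of mean RAPSN | pseudocount ε = 1 |
| `norm_variance` | `Var(x / (mean(x) + 1))` over the concatenated span | ε = 1 |

The pseudocount guards zero-coverage regions, which are common at real
junction boundaries; it makes the fold changes exactly 0 for two silent
regions and nearly scale-invariant for well-covered ones. `norm_variance`
is 0 for constant coverage and insensitive to global scaling, so it
measures within-candidate *shape*, not expression level. Mean RAPSN was
chosen as the expression estimator of a region because it is
scale-consistent with per-base coverage and robust to region length.

## Training labels

* Negative junctions: IR gap fraction > 0.5 **and** flank expression
  ratio > 10 (both strict). The conjunction keeps negatives conservative.
* Spanning positives: IR fully contained in a single evidence interval
  and flank ratio ≤ 2 (inclusive).
* Constructed TUs: per strand, the empirical distributions of the
  intergenic-length ratio `p = |ir| / (|ir| + |g_i| + |g_{i+1}|)` and the
  gene-length-difference ratio `q = ||g_i| − |g_{i+1}|| / (same)` are
  fitted over consecutive same-strand pairs with no opposite-strand gene
  in between. Sampling is empirical resampling with replacement —
  assumption-free and exactly testable, rather than a kernel smoother.
  For each gene, drawn `(p, q)` define a made-up intergenic region of
  length `L = round(p·|g|)` whose start is searched over the window
  centred on the `p`-shifted gene midpoint with half-width `q·|g|/2`
  (clamped so both flanks keep ≥ 1 bp), choosing the minimum-GC start,
  leftmost on ties for determinism. The GC criterion mimics real
  intergenic sequence, which is GC-poorer than coding sequence. A cTU is
  kept only if its made-up IR behaves like a co-transcribed junction
  (gap fraction ≤ 0.5, flank ratio ≤ 10) *and* `L ≥ 225 bp`, so cTUs
  specifically supply positives beyond the reach of ~225 bp spanning
  reads; the length floor is deliberately not applied to
  spanning-evidence positives. Genes too short to partition are skipped.

Negative and positive criteria are mutually exclusive (ratio > 10 vs
≤ 2), so the label sets are disjoint by construction. Pairs with an
opposite-strand gene in between are excluded from density fitting only;
by default they remain ordinary candidates at prediction time, with an
optional switch to force them split.

## Classifier

Min–max scaling fitted on the training set, then an RBF-kernel SVM at
customary defaults: C = 1, `gamma = 1/n_features`, uniform class weights —
no hyperparameter search. Cross-validation is stratified five-fold with a
seeded shuffle; the reported accuracy is pooled over held-out folds, whose
decision scores also feed the ROC/AUC. The final model is refitted on all
examples. Binary decisions are the sign of the decision function, making
prediction deterministic. Models persist as a versioned joblib archive
(scaler bounds, hyperparameters, support data).

## Evaluation

* **Confirmed TUs**: per evidence interval, each maximal run of
  same-strand genes fully contained in the interval; duplicates merge
  with support counts summed. Output is sorted, hence independent of read
  order.
* **Sensitivity**: a confirmed TU is recovered when all its genes lie
  consecutively within one predicted TU (every internal junction joined).
  Containment rather than exact boundary match is used because a short
  evidence read can certify a sub-run of a longer TU but never its full
  extent.
* **Similarity**: Jaccard index of the joined-junction sets of two TU
  sets over the same annotation; 1.0 when neither joins anything. This is
  symmetric, bounded in [0, 1], and 1.0 exactly on identical
  predictions.
* **Depth titration**: at each target depth `d`, `round(N·d/D_full)`
  reads are drawn without replacement (independently seeded per
  depth × replicate cell), coverage is rebuilt, features re-extracted,
  and the *fixed* trained model re-applied. At full depth this reproduces
  the full-data prediction bit-exactly. Default design: 25 replicates per
  depth; tests and the acceptance script use 8 depths × 5 replicates to
  keep a desk-scale footprint.
* **Intergenic contrast**: per-region mean RAPSN of intergenic regions
  inside TUs vs between TUs, compared with a one-sided Mann–Whitney
  rank-sum test (inside > outside) — the direction is specified by the
  co-transcription model, and no distributional assumption is warranted.
  Zero-length regions are skipped.

## Synthetic data generator

The generator emulates the signal structure the classifier exploits, under
defaults chosen as a realistic bacterial transcriptome:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 700 | ~0.7 Mb genome |
| `gene_len_mean` / sigma | 900 bp / 0.45 (log-sd) | lognormal gene lengths, floor 150 bp |
| `intra_gap_mean` | 50 bp | gaps inside TUs |
| `inter_gap_mean` | 200 bp | gaps between TUs |
| `tu_size_probs` | (0.56, 0.16, 0.10, 0.07, 0.11) | P(TU has 1..4, 5+ genes); 5+ extends geometrically |
| `coding_gc` / `intergenic_gc` | 0.40 / 0.33 | sequence composition contrast used by cTU placement |
| `depth` | 100X | target estimated depth over coding sequence |
| `expression_sigma` | 1.0 | lognormal per-TU expression spread |
| `overdispersion` | 0.3 | CV of gamma weights over 200 bp placement bins |
| `boundary_gap_prob` | 0.85 | fraction of inter-TU gaps left silent; the rest get ~3X read-through (hard negatives) |
| `antisense_rate` | 0.005 | reads flipped to the opposite strand |
| `long_read_mean_len` / `fragment_mean_len` | 225 / 170 bp | spanning-evidence length models |
| `read_length` | 50 bp | Illumina-style short reads |

Coverage is realised as discrete reads (not per-base draws) so that depth
titration subsamples genuine read sets. Expected total read mass equals
`depth × coding_length`, so realised estimated depth matches the target up
to Poisson noise. Evidence intervals are sampled inside true TU spans and
never cross a TU boundary, giving a constructive guarantee that confirmed
TUs derived from them never contradict the truth. All outputs are
byte-reproducible from (config, seed).

What the generator does **not** emulate: base-call or mapping errors,
transcription start/termination site heterogeneity beyond boundary gaps,
RNA degradation gradients, rRNA contamination, or overlapping TUs.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under idealised-but-noisy coverage, not performance on
real libraries, where junction feature distributions overlap more and
cross-validation accuracy below 1 is expected.

## Numerical choices and degenerate inputs

* ε = 1 pseudocount wherever a ratio or log of coverage means is taken.
* Zero-length intergenic regions (abutting/overlapping genes) get
  `gap_fraction = 0` and mean 0; overlapping same-strand genes form
  ordinary pairs flagged `overlapping`.
* The total coding length used by estimated depth is the union of gene
  intervals (overlaps counted once); the numerator sums both strands over
  the whole genome.
* Antisense load counts each genomic position once per strand of the gene
  bodies covering it.
* GC-minimisation ties break to the leftmost start; the cIR window is
  clamped inside `[1, |g| − L − 1]`.
* Empty annotations, single-class training sets, classes smaller than the
  fold count, empty confirmed sets, depth targets above the full depth,
  and similarity across different annotations all raise explicit errors.

## Problem sizes

The default study is ~700 genes / ~0.7 Mb at 100X (~1.3 M reads); the
full pipeline runs in seconds and the depth titration (8 × 5 runs) in
about a minute, which is why those sizes are used throughout the test
suite and the acceptance script.

## Known limitations

* One replicon per annotation; no multi-contig handling.
* No overlapping or nested TU calls; each prediction is a partition.
* No promoter/terminator signal, motif, or comparative information —
  coverage is the only evidence.
* Class balance of harvested training sets depends on the dataset; very
  shallow libraries may yield too few negatives (or positives) to train,
  in which case training raises rather than silently degrading.
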