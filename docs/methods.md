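# Methods

This note records the models, parameter choices and numerical
conventions behind `negset`, and what the synthetic experiments do and
do not establish about real data.

## Coordinates, windows and strand

All internal coordinates are 0-based, half-open, forward-strand;
readers convert at the boundary (BED is stored 0-based half-open; GFF3
1-based closed, so a GFF3 TSS is `start−1` on `+` and `end−1` on `−`).
A promoter window spans −60 to +20 around the TSS (81 nt), with the TSS
base always at window offset 60; on the reverse strand the window is
the reverse complement of the mirrored slice. Strand is mandatory on
TSS records because the window is asymmetric. Windows that run off the
sequence or contain N are skipped with a logged warning rather than
aborting the run — contig-edge TSS are normal in real assemblies — and
downstream one-hot encoding is defined only for A/C/G/T.

CDS negatives are sampled with replacement, choosing a CDS with
probability proportional to its number of valid 81-nt start positions
and then a uniform start, so every eligible genomic window is equally
likely (the least biased reading of "random windows from CDS").
Sequences are taken in coding orientation; an unstranded mode exists
(`--cds-unstranded`). Per species, `ratio` × (surviving positives)
negatives are drawn (default 2×), which guarantees enough negatives
remain after filtering to balance the dataset.

## SRS: GC-matched synthetic negatives

Per species, the empirical promoter GC fractions e_i feed a Gaussian
KDE with Scott's-rule bandwidth `n^(−1/5)·sd` (in GC-fraction units);
if all training values coincide the bandwidth falls back to 0.01 so the
sampler remains proper. Sampling draws a training value uniformly, adds
Gaussian noise of s.d. = bandwidth, and rejects draws outside [0, 1]
(rejection rather than clipping or reflection, to avoid boundary mass
spikes). Each 81-nt sequence is then synthesized i.i.d. per position
with P(G)=P(C)=g/2 and P(A)=P(T)=(1−g)/2 at its target g, so realized
per-sequence GC varies binomially around the target — matching a
*distribution* of GC rather than exact counts (an exact-composition
mode is available). With a few hundred promoters per species the
resulting negative set matches the promoter mean GC to well under 2
percentage points and the full distribution to within KDE smoothing
(two-sample KS below the 1% critical value in almost all seeded
repeats). SRS records inherit the species tag; the per-species audit
depends on this. Matching stops at mononucleotide composition:
dinucleotide/tetranucleotide structure is deliberately out of scope and
is a documented residual-bias channel.

## Redundancy reduction

All sequences are fixed-length windows, so the builtin engine defines
identity as the ungapped fraction of matching positions, computed
exactly via a one-hot dot product (blocked matrix products; the greedy
order is the input order, which is the deterministic tiebreak when all
lengths are equal). A record survives deduplication iff its identity to
every previously kept record is < 0.8; cross-filtering removes
negatives at ≥ 0.8 identity to *any* positive and never touches
positives. A k-mer prescreen can skip pairs only when the sound bound
(shared same-offset words ≥ (L−k+1) − k·d_max) proves them below
threshold; at the default threshold 0.8 with word size 5 on 81-mers the
bound is vacuous, so the prescreen provably never changes the result.
An `external-cdhit` engine shells out to `cd-hit-est` for users wanting
parity with that program's banded-alignment identity.

## Balancing and splitting

Balancing samples exactly |positives| negatives per species without
replacement (seeded; a `keep-first` debug mode exists) and fails fast,
naming the species, if any species is short. The 80/20 split is
stratified by species × label with largest-remainder rounding; strata
with fewer than 2 records go to training with a warning. Stratification
is stronger than a plain random split on purpose: per-species audits
are meaningless if a small species lands mostly in one partition.

## Models

One-hot encoding maps A/C/G/T to the four unit vectors; the RF uses the
row-major flattened 4N vector, the CNN the (N, 4) matrix. The random
forest wraps scikit-learn's; the CNN is a numpy implementation (two
conv blocks — widths 7 and 5, 32 and 64 filters, ReLU, max-pool 2 —
then dense 64 and a sigmoid output, Adam on binary cross-entropy, all
sizes configurable). Its gradients are verified against finite
differences in the test suite. Estimators follow the scikit-learn
protocol (`fit`/`predict_proba`/`get_params`), take raw sequence
strings as X, and record training metadata (dataset hash, seed,
hyperparameters). Decision threshold for class labels is 0.5, with
probability = 0.5 classified positive (documented, configurable).

Hyperparameter tuning partitions the training set into k stratified
folds and — following the tool's training protocol literally — splits
each fold internally 80/20 for fit/score, averaging the objective
(default MCC) over folds; a conventional cross-validation mode
(`standard_cv`) is available. Ties break in grid order. Transformer
models are not trained here; their probabilities enter the audit via a
validated TSV import.

## Evaluation

Sp = TN/(TN+FP), Sn = TP/(TP+FN), Pre = TP/(TP+FP), Acc, MCC, F1, and
ROC AUC as the Mann–Whitney rank statistic with ties counted ½. Ratios
with zero denominators are reported as NaN with an explicit reason —
never silently 0 — so small species cannot acquire fabricated numbers.
GC is a fraction internally and percentage points in every report.
Quartiles in the GC-by-category tables use the median-of-halves rule
(the sorted sample is split at the median; an odd middle value belongs
to neither half). Embedding export writes the CNN's penultimate-layer
activations (or passes through externally computed vectors) with label,
confusion category and GC per sequence, for projection by external
tools; random forests have no natural embedding and the export refuses
them with a hint.

## Genome scans

The scan slides an 81-nt window at stride 1 (configurable) and, in the
default attribution, adds each window's promoter probability to all 81
covered positions; a position's track value is the mean over its
covering windows. Edge positions simply have lower coverage — no
sequence is padded. This satisfies the conservation identity
Σ value(i)·coverage(i) = 81 · Σ window probabilities (skipped windows
excluded), which the tests check exactly. The alternative
`tss-offset` attribution credits each window's probability to its TSS
slot (offset 60) only; it gives much sharper peaks for
registration-sensitive models and is what the TSS-signal test uses.
Tracks are written as bedGraph with runs merged on the 6-decimal
formatted value, so a round-trip parse reproduces the file exactly.
`signal_at_tss` reports the signed difference between the mean track
value within ±flank of a TSS and the mean over the rest of the profile,
so inverted models (1−P behavior) are visible as negative deviations.

## The synthetic panels

`fixtures` generates genomes as i.i.d. background at a species GC, with
non-overlapping 81-nt promoter loci on a jittered 162-nt grid (≥ 81 nt
from the edges) and disjoint CDS intervals at background GC +
`cds_gc_shift`. Each promoter locus carries TTGACA at TSS−35 and TATAAT
at TSS−10, each base substituted with probability
`motif_mutation_rate`; strands are random. Because the hexamers are
AT-rich, the non-motif positions are drawn at a compensated composition
g′ = (81·g − 12·E[GC_motif])/69 so the *expected window GC equals the
species target* — the species-level GC is what the whole GC-matching
analysis keys on. An optional beta-distributed mode
(`promoter_gc_spread`) draws a per-locus GC target with the given
standard deviation around the species mean, emulating the wide
per-species promoter GC distributions of real corpora (real spreads are
far broader than the binomial variation of a fixed composition).
Per-species seeds derive as master seed + species index, so appending a
species never reshuffles earlier ones. Not simulated, by design:
alternative sigma-factor motif classes, codon structure in CDS, indels
in motifs.

Two canonical panels are exported:

* `gc_gradient_panel_specs` — three species at promoter GC
  0.35/0.50/0.65 (spanning the range reported for real species
  corpora), CDS +5 points; used for the ΔGC audit, the split/ratio
  contracts and the permutation-null leakage guard.
* `bias_panel_specs` — the bias-demonstration panel: five species on a
  GC gradient 0.56–0.71 in ~4-point steps (most species GC-rich, as in
  the real corpus), per-species CDS offsets of +3 to +11 points
  (matching the span of real promoter-vs-CDS ΔGC), per-locus promoter
  GC spread 0.05, motif mutation rate 0.44 (roughly the per-position
  consensus conservation of genuine σ70 elements, which keeps a one-hot
  classifier well below ceiling so that composition is a usable
  shortcut), 2000 promoters per species.

## The bias experiment and what it shows

On the bias panel, the same positives are trained once against CDS
negatives and once against SRS negatives (same seeds throughout). With
CDS negatives the validation Sp−Sn gap is a monotone function of
species GC: the AT-richest species over-calls promoters (Sn ≈ 1, Sp
depressed — its negatives are the most promoter-like in composition,
and AT-rich background chance-matches the AT-rich consensus more
often), while the GC-richest species' gap exceeds +0.05 (its high-GC,
strongly offset negatives teach the model to read composition against
its own high-GC promoters). With SRS negatives every per-species
|Sp−Sn| falls below 0.05. The acceptance test asserts exactly this
species-level signature: max |Sp−Sn| > 0.05 and a > 0.05 spread between
the GC-richest and AT-richest species under CDS; all |Sp−Sn| < 0.05
under SRS.

A note on the pooled gap: with per-species-balanced training sets and a
0.5 threshold, a reasonably calibrated classifier equalizes global
false-positive and false-negative counts, so the *pooled* Sp−Sn gap on
these fixtures is near zero by construction; the species-resolved gaps
are the robust, scientifically meaningful signature, which is why the
audit (and the test) is per-species. Published pooled gaps on real data
additionally ride on sequence structure (e.g. codon periodicity) that
the fixtures deliberately do not simulate.

These fixtures establish that the pipeline *can* induce and *can*
remove a composition shortcut in a controlled setting. They do not
establish effect sizes on real corpora: real promoters are heterogenous
in ways a planted-consensus model is not (multiple sigma classes,
TSS-annotation error, long-range composition structure), and real CDS
negatives carry reading-frame signals absent here.

## Problem sizes and determinism

Default experiment sizes (2000 promoters/species for the ΔGC target
and the bias panel; 1000/species for the permutation null) were chosen
so per-species validation metrics have standard errors of ~0.01–0.02,
small against the 0.05 decision bounds, while a full pipeline run
(panel → filters → two trained forests → audits) completes in about a
minute on one CPU. Every stochastic step takes an explicit seed and is
bit-reproducible for a fixed environment; functions reject a missing
seed rather than defaulting silently.
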