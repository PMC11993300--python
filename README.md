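# negset

Balanced multi-species promoter / non-promoter training datasets for
bacterial promoter classifiers — and audits of the GC-content bias that
the choice of negative set induces.

## The problem

Machine-learning promoter predictors are trained on experimentally
supported promoter windows (81 nt, −60 to +20 around the transcription
start site) plus a *negative* set that someone has to invent. The common
choice — random windows from coding sequence (CDS) — carries a
systematic composition artifact: bacterial CDS is GC-richer than
promoter regions (promoters are AT-rich around the σ-factor −35/−10
elements), so the negative class can be separated from the positive
class partly by GC content alone. In a multi-species model the effect is
species-dependent: the classifier over-calls promoters in AT-rich
species (high sensitivity Sn, low specificity Sp) and under-calls them
in GC-rich species (high Sp, low Sn).

`negset` implements the dataset-construction pipeline and the audit
instruments for this phenomenon:

* **windows** — extract promoter windows around annotated TSS and
  sample random CDS windows (the raw sets P0 and C0);
* **srs** — *synthetic random sequences*: per species, fit a Gaussian
  kernel density (Scott bandwidth) to the promoter GC distribution,
  draw GC targets from it, and synthesize i.i.d. sequences at those
  compositions (the raw set R0). The SRS negatives match the promoter
  GC distribution to within 2 percentage points in the mean, removing
  composition as a shortcut feature;
* **redundancy** — greedy identity clustering within each set and
  cross-filtering of negatives against positives at 0.8 ungapped
  identity (CD-HIT-style; all windows share one length, so identity is
  the fraction of matching positions);
* **assembly** — per-species balancing (exactly one negative per
  surviving positive) and a stratified (species × label) 80/20
  train/validation split;
* **models** — scikit-learn-style estimators: a random forest on the
  flattened one-hot vector (A→1000, C→0100, G→0010, T→0001; length 4N)
  and a small 1-D CNN on the (N, 4) matrix (numpy implementation),
  plus a grid-tuning protocol and an import path for probabilities
  computed by external (e.g. transformer) models;
* **evaluation** — Sp, Sn, Pre, Acc, MCC, F1 and ROC AUC, globally and
  per species; GC statistics by confusion category (TP/TN/FP/FN);
  ΔGC reports; embedding export for external projection tools;
* **genome_scan** — stride-1 sliding-window probability tracks over
  genomic sequence (bedGraph output) and TSS-local signal deviations;
* **fixtures** — synthetic multi-species genomes with planted,
  mutation-degraded −35/−10 hexamers and GC-shifted CDS intervals, so
  the whole pipeline is testable without downloads.

A `negset` command line wraps each stage
(`simulate`, `extract`, `srs`, `filter`, `assemble`, `split`, `tune`,
`train`, `predict`, `evaluate`, `scan`).

## Worked example

Three synthetic species with promoter GC means 0.35/0.50/0.65
(500 promoters each). CDS negatives sit ~5 GC points above the
promoters; SRS negatives match them:

```python
from negset import (make_species_panel, extract_all, generate_srs,
                    dedup_within, cross_filter, balance_and_merge,
                    split_dataset, train, predict_records,
                    per_species_report, delta_gc, metrics_from_records)
from negset.fixtures import gc_gradient_panel_specs

panel = make_species_panel(gc_gradient_panel_specs(n_promoters=500), seed=1)
P0, C0 = extract_all(panel.genomes, panel.tss_records, panel.cds_records,
                     ratio=2, seed=2)
R0, _ = generate_srs(P0, ratio=2, seed=3)
print(delta_gc(P0, C0).round(2).to_string(index=False))
print(delta_gc(P0, R0).round(2).to_string(index=False))
```

```
species_id  mean_gc_positives  mean_gc_negatives  delta_gc  signed_delta_gc
       spA              35.11              39.93      4.82             4.82
       spB              50.35              55.21      4.86             4.86
       spC              64.86              69.84      4.98             4.98
    pooled              50.11              54.99      4.89             4.89

species_id  mean_gc_positives  mean_gc_negatives  delta_gc  signed_delta_gc
       spA              35.11              34.97      0.14            -0.14
       spB              50.35              50.39      0.04             0.04
       spC              64.86              64.84      0.02            -0.02
    pooled              50.11              50.06      0.04            -0.04
```

GC is reported in percentage points; the CDS negatives carry a ~5-point
offset per species, the SRS negatives under 0.2. Filtering, balancing,
splitting and training a random forest on the SRS dataset:

```python
P = dedup_within(P0)
R = cross_filter(dedup_within(R0), P)
D = balance_and_merge(P, R, seed=4)
split = split_dataset(D, train_fraction=0.8, seed=5)
model = train("RF", {"n_estimators": 200}, split.train, seed=6)
preds = predict_records(model, split.validation)
g = metrics_from_records(preds)
print(f"global: Sp={g.sp:.3f} Sn={g.sn:.3f} Acc={g.acc:.3f} "
      f"MCC={g.mcc:.3f} AUC={g.roc_auc:.3f}")
for sp, m in sorted(per_species_report(preds).items()):
    print(f"{sp}: Sp={m.sp:.3f} Sn={m.sn:.3f} gap={m.sp-m.sn:+.3f}")
```

```
global: Sp=0.957 Sn=0.947 Acc=0.952 MCC=0.903 AUC=0.993
spA: Sp=0.920 Sn=0.950 gap=-0.030
spB: Sp=0.960 Sn=0.920 gap=+0.040
spC: Sp=0.990 Sn=0.970 gap=+0.020
```

With GC-matched negatives every species' Sp/Sn gap stays within ±0.05:
the model is classifying on the promoter elements, not on composition.
Training the same positives against the CDS negatives instead (see
`tests/test_acceptance.py`) produces the species-dependent bias
signature — the AT-richest species loses specificity, the GC-richest
loses sensitivity.

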