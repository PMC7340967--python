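# rnam5c

Sequence-based prediction of RNA 5-methylcytosine (m5C) sites.

m5C is a widespread post-transcriptional modification in which a methyl
group is attached to the C5 position of a cytosine. Experimental mapping
(bisulfite sequencing, miCLIP, Aza-IP) is slow and expensive, so
sequence-based classifiers are the practical way to triage candidate
sites. `rnam5c` implements the standard window-classification setup: a
candidate cytosine is represented by the 41-nt window centered on it
(positions −20…+20), the window is encoded by a battery of sequence
feature encoders, and a binary classifier separates methylated from
unmethylated windows. The package is aimed at bioinformaticians who want
the full encoder battery, leakage-safe evaluation, and a reproducible
synthetic benchmark in one place.

## Features and model

Eight encoder families, all exposed as scikit-learn transformers:

| Encoder | Idea | Dim (L = 41) |
|---|---|---|
| PSNP / PSDP / PSTP | position-specific propensity: Z = Z⁺ − Z⁻, the per-position k-mer frequency difference between classes, looked up along the window | 41 / 40 / 39 |
| Kmer (NAC/DNC/TNC) | overlapping k-mer frequencies, k = 1, 2, 3 | 4 / 16 / 64 |
| ENAC | base frequencies in a length-5 window slid 5′→3′ | 148 |
| xxKGap (mM/mD/dM) | gapped-pattern frequencies X·g·Y, X·g·YZ, XY·g·Z, cumulative over g = 1…kgap | 16·k / 64·k / 64·k |
| EIIP | electron-ion interaction pseudopotential per base | 41 |
| PseEIIP | trinucleotide frequencies weighted by summed EIIP values | 64 |
| PC-PseDNC | dinucleotide composition + λ physicochemical correlation tiers, weight w | 16 + λ |
| BE | one-hot | 164 |
| NCP + ND | ring/functional-group/H-bond indicators + cumulative base density | 164 |

Named fusion presets carry verified dimensionalities, e.g. `BEST`
(PSP + Kmer + PseEIIP + PC-PseDNC(λ=3, w=0.2)) = 120 + 84 + 64 + 19 =
**287** features. Backends: RBF-kernel SVM (default, C = 1.5,
γ = "scale"), random forest (100 trees), AdaBoost, Gaussian naive
Bayes. Evaluation: stratified 10-fold cross-validation (fold-averaged
Sn, Sp, Acc, MCC; pooled ROC/AUC) plus one-shot independent tests.
Because the propensity encoders are fit on labels, cross-validation
re-fits them inside every training fold by default — fitting them once
on all data leaks held-out labels into the features.

A synthetic generator produces labeled 41-nt windows with a planted
per-position frequency difference δ between classes (C/U enriched
upstream in positives, A/G downstream in negatives, mirroring real m5C
data), so the whole train/evaluate loop is testable without any
download.

## Worked example

```bash
rnam5c simulate -o demo --n-pos 500 --n-neg 500 --delta 0.15 --seed 7
rnam5c evaluate --preset BEST --pos demo/pos.fasta --neg demo/neg.fasta \
    --folds 10 --seed 7
```

prints

```
10-fold CV  Acc=0.9160  MCC=0.8328  Sn=0.9060  Sp=0.9260  AUC=0.9747
```

i.e. on 1,000 windows carrying a planted 15% per-position frequency
difference, the 287-feature SVM recovers the signal at 91.6% accuracy
(MCC 0.83; AUC 0.97 from the pooled held-out decision scores). Training
a deployable model and scoring new windows:

```bash
rnam5c train --preset BEST --pos demo/pos.fasta --neg demo/neg.fasta \
    -o demo/model.joblib
rnam5c predict --model demo/model.joblib --fasta demo/pos.fasta | head -3
```

```
id            prediction  score
pos_00001     m5C         1.790762
pos_00002     m5C         0.013163
```

`score` is the signed SVM margin. The same operations are available as
a library (`rnam5c.M5cSitePredictor`, `rnam5c.cross_validate`,
`rnam5c.fuse`, …); the predictor is a scikit-learn estimator and
composes with sklearn model selection.

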