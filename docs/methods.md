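# Methods

## Problem setting

A candidate m5C site is represented by the RNA window of length
L = 2ξ + 1 centered on the cytosine (default ξ = 20, L = 41; the length
is configurable but all preset dimensionalities below assume 41).
Sequences are over {A, C, G, U}; T is normalized to U on input and
degenerate IUPAC codes are rejected rather than imputed, because every
encoder here is frequency-based and silent imputation would bias the
counts. In strict mode (default) the central base must be C; the flag
exists because negative sets in the wild are not always
cytosine-centered. Positions are reported as −ξ…+ξ with 0 at the
candidate site.

## Encoders

**Position-specific propensity (PSNP/PSDP/PSTP).** For k ∈ {1, 2, 3},
per-position k-mer frequencies are tabulated separately in positives
(Z⁺, shape 4^k × (L−k+1)) and negatives (Z⁻); the propensity matrix is
Z = Z⁺ − Z⁻. A window is encoded by looking up Z at the k-mer it
carries at each position, giving vectors of length 41, 40 and 39 (120
concatenated). Frequencies are raw — no pseudocounts — so an unseen
k-mer contributes 0; each Z⁺/Z⁻ column sums to 1, each Z column to 0,
entries lie in [−1, 1], and swapping the classes negates Z exactly.
K-mer rows are frozen in lexicographic order over (A, C, G, U) and
matrices serialize to TSV so fitted encoders are portable artifacts.

Because Z is fit on labels, PSP features are supervised. Cross-validation
therefore re-fits the matrices on each training fold only
(`psp_fit="per_fold"`, the default); `psp_fit="global"` fits once on
everything first, which is simpler, is probably what older pipelines
did, and optimistically biases CV scores — both modes are implemented so
the difference can be measured.

**Kmer / ENAC / xxKGap.** Stateless frequency encoders. Kmer emits
overlapping k-mer frequencies (each k-block sums to 1; a `counts` flag
exists for diagnostics). ENAC slides a length-5 window 5′→3′ with
stride 1 and emits the 4 base frequencies per placement ((41−4)×4 = 148
components). xxKGap counts gapped patterns — mM: X·g·Y, mD: X·g·YZ,
dM: XY·g·Z — cumulatively over g = 1…kgap, so mM with kgap = 2 has
16 + 16 = 32 features. Each gap block is normalized by its own number
of valid placements (gap sizes have different placement counts, so
pooled normalization would weight them unequally); this choice is
frozen. Feature names follow `<family><kgap>Gap:<left>_<g>_<right>`.

**EIIP / PseEIIP.** EIIP values A 0.1260, C 0.1340, G 0.0806,
U 0.1335 (U inherits the thymine value). EIIP is the per-position
lookup (41 dims); PseEIIP is the elementwise product of the 64
trinucleotide frequencies with the summed EIIP of each trinucleotide —
the package tests this identity against the Kmer encoder directly.

**PC-PseDNC.** Type-1 (parallel-correlation) pseudo-dinucleotide
composition. With standardized property scales P_u (mean 0, variance 1
over the 16 dinucleotides, population convention, tolerance 1e−9),
Θ(Dᵢ, Dⱼ) = (1/μ) Σᵤ (P_u(Dᵢ) − P_u(Dⱼ))², θ_g is the mean of Θ over
all dinucleotide pairs at lag g, and the vector is
d_k = f_k / (1 + w Σθ) for the 16 compositions and
d_{16+g} = w θ_g / (1 + w Σθ) for the λ tiers — all 16 + λ components
sum to 1 by construction, and the tier mass is strictly increasing in w
whenever Σθ > 0. Defaults λ = 3, w = 0.2 (the grid-searched optimum in
this family of predictors; the search itself is reproducible with
`grid_search`). The bundled 22-property table
(`data/dinuc_properties_rna22_synthetic.tsv`) is a stand-in
compilation, marked synthetic in its filename: six base-step geometry
scales, two nearest-neighbor thermodynamic sets (ΔG/ΔH/ΔS), stacking
energy and hydrophilicity with approximate literature values, plus
seven exactly computed composition descriptors (A/C/G/U, GC, purine,
keto/amino content). Standardization makes the encoder invariant to
each scale's units; the table is swappable via `DinucPropertyTable`,
and no numeric claim in the tests depends on the specific default
values — correctness is pinned by structural invariants and a toy-table
brute-force oracle.

**BE, NCP+ND.** Both position-major, 4 values per position (164 dims at
L = 41). BE is one-hot. NCP emits ring (A/G), functional-group (A/C)
and hydrogen-bond (A/U) indicators; ND is the cumulative density — the
frequency of the current base among positions 1…i — so d₁ = 1 always
and densities lie in (0, 1].

## Fusion presets and dimensional bookkeeping

Fusion concatenates encoder outputs in spec order with globally
prefixed column names. Preset dims: PSP 120, Kmer 84, PSP+Kmer 204,
PSP+Kmer+ENAC 352, +mM2Gap 384, PseEIIP+PseDNC 83, BEST 287,
BEST+mM2Gap 319, BEST+ENAC 435; each is validated against the realized
width at fuse time. Two widths sometimes quoted for this feature family
cannot be reconciled with the constituent encoders and are deliberately
not enforced: a "476" total where the constituents (287 + 148 + 32) sum
to 467, and an all-encoders total of "1,571" where summing every block
above (with mM2Gap as the only gapped member) gives 836. The registry
reports its own verified totals.

## Classifiers and evaluation

Backends are the scikit-learn implementations: RBF-kernel SVM
(default C = 1.5 — the grid-searched value; the library default C = 1 is
a parameter away — and γ = "scale" = 1/(n_features · Var X)), random
forest (100 trees), AdaBoost, and Gaussian naive Bayes, all seeded.
No feature scaling is applied by default (every encoder output is
already bounded); an optional min-max scaler is recorded in the model
artifact when enabled.

Metrics use the miss-count convention (N⁻⁺ = positives predicted
negative, N⁺⁻ = negatives predicted positive): Sn = 1 − N⁻⁺/N⁺,
Sp = 1 − N⁺⁻/N⁻, Acc = 1 − (N⁻⁺+N⁺⁻)/(N⁺+N⁻). MCC is computed from the
contingency table — the equivalent miss-rate form
(1 − (N⁻⁺/N⁺ + N⁺⁻/N⁻)) / √((1 + (N⁺⁻−N⁻⁺)/N⁺)(1 + (N⁻⁺−N⁺⁻)/N⁻)) is
algebraically fragile and is kept only as a unit-test cross-check. A
zero MCC denominator reports 0 with a warning. ROC curves come from a
descending-score threshold sweep (SVM: signed margins; other backends:
class-1 probability) and AUC from the trapezoidal rule, which equals
the tie-corrected normalized Mann–Whitney U; constant scores yield
AUC 0.5 with a warning.

Cross-validation is stratified ("equal division" leaves fold class
balance to chance; stratification keeps per-fold metrics defined for
balanced designs) with shuffling controlled by the seed; reported
Sn/Sp/Acc/MCC are fold averages, confusion counts are fold sums, and
one ROC/AUC is computed from the pooled held-out scores. Independent
tests refit the model on the full training split first. Grid search
maximizes mean CV accuracy, either over the full Cartesian grid or
axis-wise (one coordinate sweep per parameter — the cheap
dimension-reduction protocol); ties prefer the smaller parameter value.

## Synthetic benchmark

The generator emulates the one property of real m5C data the encoders
key on: class-dependent per-position nucleotide frequencies. Each
position of each class is an independent categorical draw from a base
distribution (uniform by default) perturbed by a signed enrichment map;
the central position is always C in both classes. For a designated
nucleotide with weight ω at a position, positives get base + ωδ/2 and
negatives base − ωδ/2, and the net added mass is redistributed evenly
over the non-designated bases, so each column stays a distribution and
the realized between-class difference is exactly ωδ — which is what a
fitted PSNP matrix should recover up to binomial noise (±3·SE at the
sampled n, tested). δ values that would push any probability outside
[0, 1] raise a parameter error.

The default map plants C and U at weight +1.0 across the 20 upstream
positions (enriched in positives) and A and G at weight −0.3 across the
20 downstream positions (enriched in negatives), matching the
upstream-strong (≈5% for C) / downstream-weak (≈1.4%) asymmetry
observed in real m5C neighborhoods. Under this map, a direct
log-likelihood-ratio computation puts the Bayes accuracy at ≈0.93 for
δ = 0.15, ≈0.83 for δ = 0.10 and ≈0.68 for δ = 0.05, so the pipeline's
measured 10-fold accuracies (≈0.91 / 0.82 / 0.65 at 1,000 windows per
class) sit a few points below the optimum, as they should.

What the generator does *not* emulate: dinucleotide/trinucleotide
coupling (positions are independent, so PSDP/PSTP and PC-PseDNC carry
only the signal induced by their marginal compositions — an optional
first-order mode, `markov_rho`, repeats the previous base with
probability ρ to create genuine neighbor correlations for exercising
those encoders), transcriptome sequence context, redundancy structure
of real benchmarks, or class imbalance. Passing the recovery tests
therefore demonstrates that the machinery is correct and sensitive to
planted position-specific signal at realistic effect sizes; it does not
certify accuracy on any real transcriptome.

Fixed seeds make generation byte-identical across runs and platforms
(FASTA written with fixed 60-column wrapping and `\n` endings) and make
fold assignments and deterministic backends bit-reproducible.

## Problem sizes

The shipped evaluation scale — 1,000 windows per class for the
benchmark runs, 20 replicate datasets for the null baseline, 200 random
windows for encoder/oracle equivalence — was chosen so that binomial
noise is small relative to the tested effects (SE of an accuracy at
n = 2,000 is ≈1.1%) while the whole suite stays fast on a single core.

## Known limitations

- PC-PseDNC absolute values depend on the property table; only
  structure (normalization, monotonicity in w, oracle equivalence under
  a fixed table) is guaranteed, not agreement with any specific
  published table.
- The ENAC/BE/NCP+ND/EIIP name lists default to L = 41 until the
  encoder has seen data of another length.
- AdaBoost uses the scikit-learn default estimator count (50); the
  other defaults are pinned as documented above.
- No feature selection (mRMR-style) and no genome scanning: inputs are
  pre-extracted windows.
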