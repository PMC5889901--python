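# Methods

## Model and assumptions

`synsig` scores treatments against diseases under the signature-reversal
premise: disease-associated expression changes that a treatment pushes
back toward control levels are evidence of benefit, and changes it
amplifies are evidence of harm. The method operates entirely on
log2-scale expression matrices with two-group designs (case/control,
treated/control), assumes genes are analysed independently (no gene–gene
correlation model, equal weight per gene), and treats the two drugs of a
pair as statistically independent evidence sources when combining.

## Stage-by-stage procedure

**Disease DEGs.** Pooled-variance two-sample t-tests per gene (Welch
available via `equal_var=False`), two-sided p-values, Benjamini–Hochberg
adjustment across all tested genes, then a fold-change filter of
|Δmean| ≥ log2(min_fold_change) on the log2 data. Both filters must pass
for a gene to enter the signature. The published threshold defaults are
kept: α = 0.01 in microarray mode, α = 0.05 in RNA-seq mode, fold change
2. A moderated (empirical-Bayes) test is deliberately not used: the
plain t-test keeps the stage self-contained, and with the replicate
numbers this pipeline targets (tens per group) moderation changes little;
this is the one methodological simplification relative to common
practice, and it is confined to Step 1.

**Drug z-scores.** Each gene's treated-vs-control t statistic is mapped
to z = Φ⁻¹(F_t(t; df)) with df = n₁+n₂−2 (pooled). Under the null this
makes z exactly standard normal, so the ±1.96 regulation cut is a
two-sided 5% rule. Numerically z is computed as
sign(t)·Φ⁻¹(1 − F_t(|t|)), which is algebraically identical but exactly
odd in floating point (label swaps negate every z bit-for-bit) and
accurate in the tails.

**Pair combination.** For each unordered pair and gene,
x = −2[ln(1−Φ(z₁)) + ln(1−Φ(z₂))], pˢ = P(χ²₄ < x), z′ = Φ⁻¹(pˢ).
This is a *one-sided* Fisher combination on upper-tail probabilities:
strong joint upregulation drives z′ → +∞, strong joint downregulation
drives z′ → −∞, and independent null inputs give exactly standard normal
z′ (Fisher exactness). The formula is intentionally asymmetric between
the tails: one strongly upregulating drug saturates x regardless of its
partner, whereas one strongly downregulating drug only contributes
ln(1) ≈ 0 and leaves z′ governed by the partner. z′(−a,−b) = −z′(a,b) is
therefore *not* an identity of this statistic (z′(0,0) ≈ −0.2445, not
0); what does hold, and is tested, is that two drugs both past a
threshold combine past it in the same direction (both z < −1.96 gives
z′ < −3.0, both z > 1.96 gives z′ > 1.96). This asymmetry is
load-bearing for combination ranking: when two drugs reverse disjoint
halves of a signature, their up-pushes (on disease-down genes) pass
through the combination at full strength while their down-pushes dilute,
which is exactly why the combination can outscore each single.

**Matching and score.** Matched genes are the signature genes whose
treatment regulation is non-null — the minimal reading of "matched".
I = +1 for opposite disease/drug directions, −1 for identical.
The score is computed in the direct form Σ I·|z| / N rather than the
probit composition Φ⁻¹(Φ(mean))·k/N: the two are equal in exact
arithmetic (property-tested to 1e-10 for |mean| ≤ 6) but the composition
saturates in floating point once the signed mean exceeds ≈ 8. p_k is
still reported for reference.

**Ranking.** For each pair, the best treatment is the maximum of the
three scores, required to be strictly positive ("choose max, then
require > 0"). The combination verdict requires strict superiority over
both singles; ties go to single drugs (conservative: a combination
should earn its extra complexity), and a tie between the singles goes to
drug A. Records with k = 0 or N = 0 are flagged and excluded from
ranking rather than scored 0, distinguishing "no evidence" from
"net-zero evidence".

## Numerical choices

- All probabilities entering a logarithm or normal quantile are clamped
  to [1e-15, 1−1e-15], bounding |z| and |z′| at ≈ 7.94. The constant is
  shared across stages.
- Degenerate genes: zero variance in both groups with equal means give
  t = 0, p = 1 (never called); zero variance with unequal means give the
  maximal clamped |z|.
- Missing values are rejected at load time; imputation is out of scope.
- Pair enumeration, batch scoring, and all file outputs are
  deterministically ordered (lexicographic), so identical inputs produce
  byte-identical outputs.

## Synthetic data generator

The generator emulates the two input kinds with planted ground truth:
per-gene baselines ~ U(4, 12) log2 units (a typical microarray intensity
range), i.i.d. Gaussian noise, and additive shifts on planted genes.
Default condition: 5,000 genes, 200 planted DEGs (2% up, 2% down),
effect size 2.0 log2 units, noise sd 0.5, 25 case / 25 control — a
deliberately strong, well-powered signature (per-gene t ≈ 14) so that
pipeline behaviour, not DEG-calling power, is what end-to-end tests
exercise. Drug datasets use the same sample sizes and noise, with modes
*reverse*, *mimic*, *null*, and *partial(p)*; a `target_genes` argument
restricts a drug's action to a signature subset.

Mimic mode is generated as the exact mirror image of the same-seed
reverse dataset about the gene baselines. Because the noise is zero-mean
Gaussian this is distributionally indistinguishable from fresh draws,
and it makes the reverse/mimic score symmetry hold to floating-point
rounding (~1e-12 on scores of magnitude 8) rather than only in
expectation.

What the generator does **not** emulate: gene–gene correlation, batch
effects, count-level (negative binomial) RNA-seq noise, probe effects,
dose/time response. Passing tests therefore demonstrate correctness of
the statistical machinery under idealised independent Gaussian data, not
robustness to real-data artefacts.

All randomness uses numpy's seeded PCG64 generator; identical seeds give
bit-identical matrices across platforms.

## Problem sizes used in validation

The automated checks run at: 10,000 genes for null-calibration KS tests;
1,000 randomised match tables for the score identity; a 49×49 to 61×61
grid on [−6, 6]² for the closed-form chi-square oracle; the 5,000-gene
reference condition over 10 seeds for disjoint-halves synergy recovery;
and a 10-gene, 2+2-sample toy instance (noise sd 0.1, so that a
signature can survive BH at df = 2) for the symbol-by-symbol
re-evaluation of the whole pipeline.

## Known limitations

- The one-sided combination's tail asymmetry means down-synergy is
  systematically harder to detect than up-synergy; this is a property of
  the scoring statistic itself.
- Combinations are pairs only; the combination formula is defined for
  two evidence sources (χ² with 4 df).
- Equal gene weights: no attempt to upweight driver genes.
- The disjoint-halves synergy margin under the reference condition is
  small (mean ≈ +0.08, sd ≈ 0.06 across seeds), so individual simulation
  runs can occasionally rank a single drug first; recovery is reported
  as a fraction over repeated runs.
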