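# Methods

`cernaflow` implements the post-quantification analysis of a five-group rat
renal-interstitial-fibrosis (RIF) treatment experiment as a reusable,
testable pipeline. The five groups are NC (normal control), OC (untreated
disease model), LK and HK (low/high-dose herbal treatment) and LOS
(losartan). Inputs are gene-by-sample count matrices for three RNA layers
(mRNA, miRNA, lncRNA), a predicted miRNA→target map, GMT pathway sets,
per-animal histology readouts and qPCR Ct tables. Upstream read processing
(QC, trimming, alignment, quantification) is out of scope: matrices arrive
already quantified.

## Histopathology and qPCR scores

* **GSI** (glomerular sclerosis index): 40 glomeruli per animal are graded
  0–4 by the sclerosed fraction of the cross-section; the index is
  `(N1·1 + N2·2 + N3·3 + N4·4)/40`, a weighted mean in [0, 4]. The score is
  permutation-invariant in the 40 grades and monotone in each grade.
* **TII** (tubulointerstitial injury index): a step function of the percent
  injured interstitial area — grade 0 only for no deformity, then 1 (<10%),
  2 (<25%), 3 (<50%), 4 (<75%), 5 (≥75%). Boundary percentages (exactly
  10/25/50/75) are assigned to the higher grade, the only reading consistent
  with the closed top bin "≥75"; the rule is applied uniformly.
* **2^−ΔΔCT**: per sample, ΔCT = target Ct − reference-gene Ct (GAPDH);
  ΔΔCT subtracts the calibrator group's mean ΔCT (NC by default); relative
  expression is 2^−ΔΔCT, so the calibrator averages 1 and each extra cycle
  halves expression. Relative expressions compose along calibrator changes:
  rel(A vs C) = rel(A vs B)·rel(B vs C).
* **Group summaries**: mean ± sample (n−1) SD per group, with tiered marks
  against the model control (`*`) and the normal control (`#`) at
  p < 0.05/0.01/0.001 from a two-sided Welch t-test. No multiplicity
  correction is applied across the five-group layout; with the small animal
  groups these tables are descriptive, and the gap is deliberate.

## Normalization and differential expression

Counts are normalized to CPM (each sample column sums to 10⁶); tests,
clustering and PCA work on log2(CPM + 1). The pseudocount of 1 guards zero
counts and is symmetric in the fold change: FC = (mean_B + 1)/(mean_A + 1)
on linear group-mean CPM, so swapping the contrast inverts FC exactly.

A feature is called **up** when FC > 1.5 and p < 0.05, **down** when
FC < 0.67 and p < 0.05, else **ns**; both inequalities are strict, so FC of
exactly 1.5 or 0.67 is not significant. The p-value is a two-sided
Student (pooled-variance) t-test on log2 CPM. The pooled test was chosen
over Welch after measurement: at n = 3 per group Welch's Satterthwaite
approximation is visibly conservative (type-I ≈ 0.033 at nominal 0.05 even
on exactly normal data), while the pooled test is exact under the
generator's equal-variance design and keeps the DEG rule's null rate
calibrated. No multiple-testing correction enters the call — the rule is a
raw-p rule — but a BH-adjusted column is emitted for information.

The DEG-count table reports, for every unordered pair of groups, the number
of called features; it is symmetric by construction. Sample structure is
summarized by Ward hierarchical clustering on Euclidean distances of
log2-CPM columns (deterministic linkage, Newick export) and by PCA: PC1 of
the feature-centered log2-CPM matrix, its sign fixed by the convention that
the OC-group mean coordinate is positive (a principal axis has no intrinsic
sign; the convention makes runs comparable and points "worse pathology"
positive). PC1 is then Pearson-correlated with a per-animal pathology score
(GSI). t-SNE is deliberately not implemented: it is a stochastic
visualization with no downstream role.

## Pathway over-representation

For a DEG set of size n in a universe of N quantified features, a pathway
with K universe members and k differential members is scored by the
one-sided Fisher exact test, p = P(X ≥ k) for X ~ Hypergeometric(N, K, n).
Over-representation semantics force the upper tail. The universe is the set
of features quantified in the layer under test — what was measurable — not
the genome. A pathway is *reported* when p < 0.05 and k ≥ 3; BH-adjusted
p-values are emitted but do not enter the reporting rule. A differential
gene absent from the universe is an error rather than a silent drop, which
would otherwise inflate the background. The package also ships an
independent oracle (`hypergeom_tail`, direct log-space summation of the
hypergeometric mass via `lgamma` and `logsumexp`) used to cross-check the
`scipy`-based p-values; the two share no code.

## Coexpression and ceRNA network inference

The adjacency between two features is a power of the Pearson correlation of
their expression profiles, a(i,j) = |r(i,j)|^β. The soft power β defaults
to 1 because the downstream rule is pure thresholding — only the strongest
correlations (|r| ≥ 0.8, inclusive) enter the coexpression graph — but β is
configurable for WGCNA-style soft thresholding. Correlation p-values use
the exact t transform t = r·√((n−2)/(1−r²)) with n−2 df; BH adjustment is
applied within each edge family (the hypotheses actually examined
together), and edge weights are −log10(adjusted p).

Three sign rules coexist, matching how each evidence type works:

* plain coexpression uses |r| ≥ 0.8 (unsigned);
* miRNA→target edges require the pair to appear in the supplied target map
  **and** r ≤ −0.8 (signed: miRNAs repress, so only negative correlation is
  evidence; positive correlation of a predicted pair is discarded);
* lncRNA–miRNA edges require r ≤ −0.8 (correlation-only: no lncRNA target
  map is assumed, though an optional map filter exists, off by default);
* lncRNA–mRNA edges require r ≥ +0.8.

The +0.8 lncRNA–mRNA requirement is an inference from sponge logic rather
than an independently stated rule: a lncRNA that sequesters a miRNA rises
and falls with the miRNA's targets. It can be switched off
(`require_lnc_mrna_positive=False`), in which case the unsigned rule
applies. A **sponge triad** (lncRNA, miRNA, mRNA) is emitted when all three
legs pass; a filtered network view keeps edges with adjusted p < 0.05 and
the triads those edges still support. Exports are Cytoscape-loadable SIF
plus an attribute TSV and a triad table.

Thresholds always apply to the raw sample correlation; adjusted p enters
only the significance view. Applying the cut to adjusted quantities instead
is a defensible alternative, so both the thresholds and the adjusted-p cut
are configurable.

## The synthetic data generator

Real data from this design are per-animal sequencing runs that cannot be
redistributed, so the package ships a generator that emulates the study's
statistical structure with known ground truth. It is first-class, tested
code: every analysis claim in the test suite is a recovery statement
against the generator's manifest.

**Counts.** Negative binomial via gamma–Poisson: counts ~ Poisson(λ),
λ ~ Gamma(1/φ, μφ), giving variance μ + φμ². Feature baselines are
log-normal around `baseline_mean` (default 1000, log2 SD 1.0, floored at 50
counts so no feature is dominated by Poisson discreteness).

**Treatment axis.** A dose profile multiplies every planted effect:
NC = 0, OC = 1, LK = 0.7, HK = 0.2, LOS = 0.4. High-dose treatment ends
nearest normal and the model control farthest, which is the qualitative
pattern the DEG-count and PC1 analyses must reproduce. The profile values
are free parameters: the tests need a monotone severity axis, not the true
effect sizes.

**Planted differential mRNAs.** `n_de_mrna` (60) features carry
±`effect_log2fc`·dose (default |log2FC| = 2 at full dose), alternating
directions.

**Repression pairs and sponges.** Each planted pair shares a per-sample
latent regulator z = standardized dose + jitter (SD 0.3). The miRNA loads
+τ·z, its target −τ(√c·z + √(1−c)·ε), so the sample Pearson correlation
concentrates near −√c, with c = `repression_coupling` (default 0.99) the
fraction of target variance explained by the miRNA. A sponge lncRNA loads
−τ·z plus small noise: negative with its miRNA, positive with the target —
the ceRNA sign pattern. Making z dose-anchored (rather than pure noise)
keeps within-group variance small, so Ward clustering and PCA still recover
the groups while the correlation structure holds.

**Structural features' scale.** Pair and sponge features sit at a fixed
mid-range baseline (300 counts) with low dispersion (0.03). Both choices
are load-bearing: per-gene dispersion heterogeneity is the norm in bulk
RNA-seq, and a latent swing on high-baseline features would dominate
library sizes — CPM is compositional, so a handful of exploding features
would distort every other feature's fold change.

**Noise level.** `nb_dispersion` defaults to 0.12 (per-sample log2 SD
≈ 0.5 at baseline, a realistic animal-to-animal CV²). The value is chosen
so that at n = 3 per group a significant t-test already implies a >1.5-fold
observed change: below ~0.08 the fold-change gate truncates the DEG rule's
null rate well under the t-test's level, and above ~0.15 the power at
|log2FC| = 2 drops below the recovery targets. 0.12 balances the two
(measured null rate ≈ 0.037, recall ≈ 0.95).

**Decoys and pathways.** The target map mixes true pairs with decoy entries
(`decoy_target_fraction`, default 0.5) whose targets are drawn from inert
(non-planted) mRNAs, so the map filter is testably non-vacuous. Decoy
targets are deliberately not dose-responsive: a dose-responsive decoy would
be genuinely anti-correlated with a dose-responsive miRNA through the
shared treatment axis, and "zero decoy triads" would measure the dose
confound instead of the filter. One pathway of 20 genes is packed with 15
planted differential mRNAs (the planted enriched pathway); the remaining 19
pathways are uniform draws from the layer.

**Histology and qPCR.** Each animal (identified with its RNA sample)
receives 40 glomerulus grades drawn per-group from Binomial(4, 0.05 +
0.85·dose) — expected GSI rises from ~0.2 (NC) to ~3.6 (OC) — plus injury
and Masson area percentages increasing with dose. Grade distributions are
overridable per group (any probability vector over grades 0–4). The Ct
table covers a fibrosis marker panel (Tgfb1, Smad3, Col1a1, Col1a2, Fn1,
Acta2 up with severity; Smad7, Tmlhe down) around a flat GAPDH reference,
with ±2 log2 units at full dose and 0.15 cycles of noise.

**Seeding.** One master seed spawns independent child streams (latent
regulators, one per RNA layer, target map, pathways, histology, qPCR), so
resizing one layer never perturbs another, and identical configs give
byte-identical TSV output.

**What the generator does not emulate.** Library-size variation between
samples, GC/length biases, zero inflation, batch structure, correlated
background co-regulation beyond the planted pairs, and any real rat
biology: feature ids are synthetic. Passing recovery tests therefore shows
the pipeline's rules behave as specified under the assumed generative
model, not that they would recover biology from real kidney data. A known
side effect of the dose-anchored latent: planted pairs from different
triads correlate with each other through the shared treatment axis, so
sign-consistent cross-triads (lncRNA_i, miRNA_j, mRNA_j) appear beyond the
planted list. They are genuine patterns of the generative model, neither
planted nor decoy, and recovery metrics ignore them.

## Numerical choices and degenerate inputs

* Correlations clip to [−1, 1]; |r| = 1 maps to p = 0 and adjusted p is
  floored at 1e−300 before −log10 so weights stay finite.
* Constant features are excluded from correlation with a warning; an
  all-constant matrix, fewer than 3 shared samples, all-zero sample
  columns, constant pathology scores, and group sizes below 2 are errors.
* Zero-variance t-tests (identical groups) give NaN p and are called `ns`.
* BH adjustment delegates to `statsmodels`; tests verify it against a
  brute-force sort-based oracle.
* Ties in enrichment ranking are broken by pathway name (stable sort), so
  outputs are order-deterministic.

## Problem sizes

Default study conditions: 5 groups × 3 animals, 600 mRNAs, 150 miRNAs, 200
lncRNAs, 60 planted differential mRNAs, 15 repression pairs (5 of them in
sponge triads), 15 decoy map entries, 20 pathways of 20 genes. Calibration
checks use 50 replicate null simulations of 500 features; recovery checks
use 20 independent seeds. These sizes give each Monte-Carlo estimate a
standard error well inside its acceptance margin while the whole suite and
the acceptance script each run in well under a minute of compute.

## Known limitations

* The DEG rule is the published fold-change + t-test criterion, not a
  dispersion-modelled test (no shrinkage, no exact NB test); at n = 3 its
  power profile is what the criterion implies.
* The enrichment universe choice (quantified features) and the unadjusted
  DEG p-rule are fidelity choices, not statistical recommendations.
* The ceRNA construction is correlation + sign pattern + target map; it
  does not model binding-site stoichiometry or partial correlation, and a
  shared upstream driver can satisfy the sign pattern without any direct
  interaction.
* Real TargetScan/miRBase/KEGG queries are out of scope; maps and gene
  sets arrive as files.
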