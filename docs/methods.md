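# Methods

This note documents the models, defaults and numerical choices behind
`myoquiesce`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## The classification problem

The myometrium (uterine smooth-muscle wall) transitions from a quiescent (Q)
program to a contractile, nonquiescent (NQ) program at labor. Clinical labor
criteria (contractions, cervical change, membrane rupture) do not always
reflect that molecular state, particularly in preterm birth. The package
classifies biopsies molecularly: a transcript signature is derived from
unambiguous reference samples (term labor = NQ, term not-in-labor = Q),
unlabeled samples are projected into the signature's PCA space and called
along PC1, and a parsimonious two-gene surrogate — the ATP2B4/ATP2A2
expression ratio — provides the same call from a pair of qPCR assays.

## Clinical scoring

Scores are a deterministic, total mapping of raw fields: gestational age
dichotomized term (1, > 37 wk) / preterm (0, < 34 wk); contractions 0
(absent), 1 (irregular without cervical change, or receded after tocolysis),
2 (regular with cervical change); dilation 0–10 cm; membranes 0/1; Triple I
0/1 with `unknown` propagated as missing. Deliveries at 34–37 wk receive
`indeterminate` rather than a coerced 0/1: the dichotomy is undefined there
and we refuse to guess. Group assignment follows the five delivery-group
predicates only; contradictory flag combinations (e.g., provider-initiated
with active labor) are `unclassified` rather than forced.

## Synthetic cohorts

The generator emulates a bulk RNA-seq cohort of detected (post-filter)
transcripts with a planted Q/NQ contrast. For gene i and sample j,

    k_ij ~ NB(mean = s_j · q_i · 2^(lfc_i · z_j) · 2^(b_ij),  dispersion α_i)

with z_j the latent NQ indicator, s_j ~ exp(N(0, 0.3)) library-size factors,
b_ij per-gene batch shifts (sd 0.1 log2 units; term samples share one batch,
mirroring a design in which the reference contrast is single-batch), and the
dispersion trend α(q) = a0/q + a1 with a0 = 5, a1 = 0.05. Baseline means are
2^N(8, 2) floored at 10 — "detected transcripts" at roughly 30M-read depth;
genes below a detection floor are not simulated because the analysis assumes
a detection-filtered matrix. Default design: 5 TL + 5 TNL reference samples
and 21 preterm samples (4 NQ, 17 Q), 20,000 genes, 21% of genes planted with
|log2 FC| ≥ log2 1.5 (floor + exponential tail, scale 0.6). The anchors are
always planted (ATP2B4 −1.5, ATP2A2 +0.9 log2 units in NQ, baselines
1500/500 so the quiescent ratio is 3.0); the qPCR reference genes B2M and
RPL30 are always null.

qPCR wells are generated as Ct = c0 − log2(normalized expression) + N(0,
0.15) per well, two wells per (sample, assay), c0 = 32; at zero noise the
comparative 2^(−ΔC) statistic equals the planted per-sample ratio exactly,
and doubling expression lowers Ct by one cycle.

Clinical covariates are drawn from a conditional-probability table, not a
causal model: a sample's *clinical* laboring state equals its molecular
phenotype flipped with probability `mismatch_rate` (default 0.2 — of order
the clinical/molecular disagreement seen in preterm cohorts), and
contractions, dilation, membranes and Triple I are then emitted conditional
on that state (defaults in `SimulationConfig`; they are conventions of the
generator, not literature estimates). Only preterm samples receive a
Triple I assessment; term samples carry `unknown`.

What the generator does **not** emulate: GC/length biases, isoform
structure, outlier samples, correlated gene modules beyond the planted
contrast, batch-confounded designs, or qPCR amplification-efficiency
deviations. Passing tests therefore demonstrate that the statistical
machinery is correct and calibrated under the stated model — not that the
biological effect sizes of any real cohort will be reproduced.

## Differential expression

A deliberately compact NB pipeline implements the signature criteria:

* **Size factors** — median across all-nonzero genes of k_ij / geometric
  mean, rescaled to unit geometric mean (the plain median of ratios).
* **Dispersions** — within-group method of moments on normalized counts,
  α̂ = max((var − μ)/μ², 1e-8), pooled across contrast groups by degrees of
  freedom, then blended 50/50 with a trend α(μ) = a0/μ + a1 fitted by
  non-negative least squares across genes. The blend stabilizes gene-wise
  noise at small n while letting genuinely atypical genes deviate.
* **Test** — gene-wise NB GLM with log link, log s_j offset, group indicator
  and optional additive batch indicators, fitted by vectorized IRLS (fixed
  dispersion); Wald z on the group coefficient, two-sided normal p, BH
  adjustment over tested genes. Genes that are all-zero in one group are
  flagged `separated`; their displayed log2 FC uses 0.5-pseudo-counted group
  means while the p-value remains the model's.
* **Filter** — |log2 FC| ≥ log2(1.5) and q < 0.1, split into up/down.

Divergences from full-featured DE packages are intentional and documented:
no independent filtering, no outlier (Cook's-style) replacement, no shrunken
fold-change estimator, Wald rather than LRT. Validity is established by
calibration (null p-values uniform, KS < 0.02 at 20,000 genes; type-I error
0.04–0.065 at α = 0.05 in the 5+5 design) and parameter recovery
(sensitivity ≥ 0.8 at |log2 FC| ≥ 1 with observed FDR ≤ 0.15 on default
cohorts), plus a fold-change cross-check against an independent NB
implementation on a small cohort.

## PCA phenotyping

Expression enters as log2(size-factor-normalized count + 1) — a standard
variance-stabilizing choice; the transform is a documented default, and
correlation-PCA (`scale=True`) is available. PCA is fitted on the signature
genes of the labeled reference samples only; components are oriented by the
labeled centroids (NQ centroid below Q on PC1), never by an eigen-solver's
sign convention. New samples are transformed with the training center/scale/
loadings — no refit, no imputation (missing signature genes are an error).
Calls use the nearest reference centroid on PC1 with the midpoint as the
boundary, ties to NQ; an optional transitional band (fraction of the
inter-centroid distance) reflects that borderline samples may occupy a
transition state. Spearman correlations of PC1 with clinical scores use
midranks; p-values use exact permutation enumeration for n ≤ 10 and the
t approximation above.

## Enrichment

Signal-to-noise ranking (μ_A − μ_B)/(σ_A + σ_B) with each group sd floored
at max(σ, 0.2·|μ|, 1e-8) — the desktop-tool convention; ties broken by gene
symbol for determinism. The enrichment score is the signed extremum of the
weighted KS running sum (hits weighted by |metric|^p / Σ|metric|^p, default
p = 1; misses −1/(N − m)); a set spanning the whole universe is scored
against the positional CDF (ES = 0 for equal weights). Phenotype-label
permutations regenerate the ranking each time; the nominal p uses the
add-one rule within the same-sign permutation stratum, so p is never 0 and
is uniform under the null. NES divides by the mean same-sign permutation
|ES|; FDR uses the sign-stratified ratio of permutation to observed NES
tails. With fewer than 7 samples per group the permutation space is coarse
(252 splits at 5+5) and a warning recommends gene-set permutation, which is
available as a flag. The "signed FDR" ranking used for single-set enrichment
plots is sign(log2 FC)·(−log10 q) with q floored at 1e-300. Network
construction stops at the overlap-coefficient edge list (|A∩B|/min(|A|,|B|)
≥ 0.1 between sets passing p < 0.005 and FDR < 0.1).

## Ratio classifier

Raw feature counts are the default ratio mode: within a sample every
sample-level scale (library size, size factor) cancels, so raw and
normalized modes are provably identical, and gene-length effects cancel
because the same two genes are compared across samples. qPCR wells are
averaged on the Ct scale (arithmetic mean of Ct = geometric mean of linear
quantities); the reference normalization uses the mean of the two
reference-gene Cts (log2 of their geometric mean), and the references cancel
in the two-gene ratio itself. AUC is the tie-adjusted Mann–Whitney
concordance of "lower ratio ⇒ NQ" (midrank formula, exactly the pairwise
concordance probability). The operating threshold maximizes Youden's J with
ties broken toward the higher threshold, favoring NQ sensitivity — the
selection criterion is a documented default (`--threshold` overrides it with
a fixed cutoff), and the NQ side of the rule is inclusive (R ≤ τ). The
correlated-gene panel reports Pearson r ≥ 0.95 (one-sided) against either
anchor on log2-normalized expression.

## Pipeline and reproducibility

All randomness flows from one seed through numpy's PCG64 generator; the RNG
algorithm is named in the manifest and config echo. A fixed config + seed
yields byte-identical outputs, manifest included — stage timings are logged
to stderr only, deliberately kept out of the manifest. Outputs are TSV with
`#` provenance headers (tool version, seed); the manifest additionally
records input hashes, stage status and headline statistics. Config files are
validated exhaustively (all violations reported at once, unknown keys
rejected). On failure the manifest records the failing stage and partial
outputs are retained.

Problem sizes used by the test suite: the calibration and full-scale checks
run at the design size (20,000 genes × 31 samples — a full pipeline run
takes seconds); replicate-heavy recovery checks (50 cohorts, 100-sample Ct
recovery) use a few hundred genes, which is sufficient because the
quantities under test concern the anchor genes and per-sample statistics,
not genome-wide behavior.

## Known limitations

* The DE stage is intentionally minimal; on real data with outliers or very
  shallow libraries a full-featured NB package will be more robust.
* The PC1 two-cluster call assumes the reference contrast dominates the
  signature variance; strong confounders (site, incision, severe batch) in
  the projected samples are not corrected beyond the DE batch covariate.
* Phenotype permutation p-values are coarse below ~7 samples per group; the
  gene-set permutation flag is the recommended fallback there.
* The clinical emission model is a convenience for testing the scoring and
  correlation stages, not an epidemiological model of labor.
* qPCR is modeled with ideal amplification efficiency; no standard-curve
  quantification.
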