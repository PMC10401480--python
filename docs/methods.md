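# Methods

## Model and procedure

`surfnom` screens a four-group bulk RNA-seq cohort (benign prostate,
localized prostate adenocarcinoma "pca", castration-resistant
adenocarcinoma "crpc", neuroendocrine "nepc") for genes and transcript
isoforms that encode cell-surface proteins and are expressed specifically
in NEPC. The procedure is a sequential filter, not a joint model: each
stage applies one interpretable rule, and every feature's fate (stage and
reason code) is recorded, so the output is an auditable funnel rather than
a ranking score alone.

### Abundance units

TPM is rate-normalized: per sample, `rate_i = count_i / length_i` and
`TPM_i = rate_i / Σ rate × 1e6`, so columns sum to 10⁶ exactly whenever a
sample has any reads. FPKM is `count · 1e9 / (length · N)` with `N` the
sample's total counts; the two are proportional within a sample. The
effective length is the annotated length — no fragment-length correction —
because the pipeline only ever compares a feature against thresholds or
against itself across groups, where a constant per-feature length factor
is immaterial. Which unit feeds the presence filters is a config choice
(`abundance_unit`, default TPM).

### The NB Wald engine

Counts are modeled as NB with `Var = μ + αμ²`.

* **Size factors** are median-of-ratios: `s_j = median_i count_ij / g_i`
  over the features with nonzero counts in every sample (`g_i` = geometric
  mean across samples). There is no pseudo-reference fallback: if no
  feature is expressed everywhere, the data are too sparse for this
  normalization and the engine raises instead of silently degrading.
* **Dispersion** is method-of-moments on normalized counts pooled within
  groups: `α̂ = max(floor, (v̂ − m̂)/m̂²)` with `v̂` the within-group
  variance on `N − G` degrees of freedom and `m̂` the grand mean. The
  floor is 1e-8 (numerical, not statistical: it keeps the NB likelihood
  well-defined for under-dispersed features). No empirical-Bayes shrinkage
  is applied; that keeps the estimator a closed-form, oracle-testable
  quantity at the price of noisier per-feature α̂ at small n (see
  Limitations).
* **Per-group means** are fitted by Newton iteration on `β = ln μ` with α
  fixed; score `Σ (k−m)/(1+αm)` and observed information
  `Σ m(1+αk)/(1+αm)²`, steps clipped to ±3 for global stability,
  convergence at |step| < 1e-12 (≤100 iterations; in practice <15).
* **The Wald statistic** uses the expected (Fisher) information
  `I = Σ m/(1+αm)` at the MLE: `Var(β̂_num − β̂_den) = 1/I_num + 1/I_den`,
  `z = log2FC / SE`, two-sided normal p. Expected rather than observed
  information is used because it is positive by construction and agrees
  with the observed one to O(n^-1/2); the test suite bounds the resulting
  z against an independent numeric MLE oracle (|Δz| < 0.05, measured
  ~1e-5).
* **Zero groups.** Both groups all-zero → log2FC 0, p 1, flagged. One
  group all-zero → the fold change is capped at ±10 (`lfc_cap`,
  configurable) and the statistic computed from the capped fit, flagged;
  this keeps such features testable without infinite estimates.
* **Multiple testing** is Benjamini–Hochberg within each pairwise
  contrast independently; contrasts are not pooled. The step-up is
  implemented directly (sorted cumulative minimum) and checked against
  brute-force enumeration and statsmodels.

Independent filtering of low-count features before testing is off: the
cascade's own TPM presence filters play that role downstream.

### The cascade

Stage order is fixed: (1) NEPC-vs-benign DE gate (padj < 0.05, FC ≥ 2.0)
plus benign/NEPC presence gate at 1 TPM; (2) NEPC-vs-PCa DE gate
(padj < 0.1, FC ≥ 1.5) plus the symmetric presence gate; (3) surfaceome
restriction; (4) tissue-breadth gate (drop when median TPM > 3.0 in ≥ 5
tissues); (5) NEPC-vs-CRPC DE gate (padj < 0.1, FC ≥ 1.5). Design choices:

* The presence rule names no aggregate; the per-group **median** TPM is
  used (configurable to mean), consistent with the explicit median rule of
  the tissue-breadth stage and robust to single outlier samples.
* Boundary conventions are exact: strict `<` on padj, inclusive `≥` on
  fold change, strict `>` on the 3.0 TPM tissue cut, `≥ 5` tissues drops.
* The DE gates act on the signed log2FC — the pipeline nominates
  *overexpressed* features only.
* Surfaceome membership is the **union** ("any of") of the annotation
  sources, matched verbatim (no case folding, no alias resolution —
  alias maps are database-version-dependent and are the caller's
  responsibility; unannotated features are counted in a warning).
* Ranking of the final candidates: NEPC-vs-CRPC log2FC descending, ties by
  NEPC-vs-benign padj ascending, then lexical feature id — an arbitrary
  but total order, so output is byte-reproducible.
* When one stage's DE and presence rules both fail, the recorded reason
  follows the precedence padj → log2fc → `<ref>_tpm_high` →
  `nepc_tpm_low`.
* An optional tissue-exclusion list for the breadth gate exists but is
  empty by default.

The isoform cascade is the same engine on transcript counts with
surfaceome membership inherited through `tx2gene`. The NB engine is used
for the transcript contrasts as well; a read-level isoform-deconvolution
model (Cuffdiff-style) is deliberately out of scope, since it requires
alignments rather than count matrices. Candidates whose parent gene was
not nominated at gene level are flagged `isoform_specific`; because the
gene-level result is a separate run, it is passed in as an optional
argument (`gene_candidates` / `--gene-candidates`), and without it the
flag column is computed as if no gene had passed.

## The synthetic cohort

The generator emulates the statistical structure the cascade assumes, with
every parameter in `SimConfig`:

* 2,000 genes; 20/20/20/12 benign/pca/crpc/nepc samples (a scaled-down
  echo of a 66/68/72/27 clinical cohort); 30 tissues; NB dispersion
  α = 0.2; size factors log-uniform in [0.5, 2]; lengths uniform in
  [500, 5000] bp (planted classes fixed at 2,000 bp so their TPM↔count
  conversion is exact).
* Background baseline count means are log-normal, `ln μ ~ N(ln 2500, 1)`,
  i.e. a ~8–16M-read library concentrated on 2,000 genes. The scale is
  chosen so that the pipeline's 1 TPM presence threshold corresponds to a
  resolvable count (~8 reads at 2 kb): a real transcriptome dilutes TPM
  across tens of thousands of genes, and at 2,000 genes a realistic
  library depth per gene is what keeps TPM thresholds and count-level
  power in the same regime they occupy on real data.
* Planted classes are specified in TPM and converted through the
  background rate pool: true targets sit at 0.4 TPM in benign/pca/crpc and
  8× that (3.2 TPM) in NEPC — fold change 8; CRPC-shared decoys are high
  in both NEPC and CRPC; non-surface decoys have the target profile but no
  annotation; broad-tissue decoys exceed 6 TPM in 8 of 30 tissues;
  benign-leaky decoys sit at 3 TPM in benign (still 8× higher in NEPC);
  isoform-switch genes are flat at 6 TPM in all groups. Each class is
  therefore passed/failed by construction at exactly one stage, with ≥3×
  margin to every threshold, and the truth table records the expected
  stage and reason.
* Tissue medians are generated directly (the cascade consumes only
  medians) with 10% log-normal noise; background genes mirror their
  baseline TPM, so they are realistically "broad" — they are removed at
  stage 1 regardless.
* Isoforms: every gene carries one transcript with its full counts;
  switch genes carry two, split by per-sample binomial thinning of the
  gene counts (which preserves both the gene total exactly and the NB
  dispersion), at proportions 0.1/0.9 outside NEPC and 0.9/0.1 inside.
  The switch transcript thus has a planted fold change of 9 and a benign
  TPM of 0.6 — nominated by the isoform cascade while its flat parent gene
  is not.
* All randomness flows from one master seed through a fixed
  `SeedSequence` stream layout; identical seeds give byte-identical
  files.

What the generator does **not** emulate: batch and library-prep effects,
GC/length bias, correlated genes, alias/identifier noise, per-tissue
sample-level variation (medians are drawn directly), and read-level
phenomena. Passing tests therefore demonstrate that the pipeline's logic,
statistics and bookkeeping are correct under its stated model — not that
the thresholds would achieve the same sensitivity/specificity on a real
cohort, where effect sizes and annotation quality are less favorable.

## Problem sizes and numerical choices

The reference verification runs 40 seeded cohorts for the gene cascade and
decoy checks, 20 for the isoform branch, and 20 null simulations for
type-I error (the whole acceptance script completes in ~15 s on one core).
The engine's Newton fit is vectorized across features; a full three-
contrast cascade on 2,000 × 72 counts takes ~0.1 s. Measured behavior at
these sizes: type-I error 0.066 at nominal 0.05 (the expected mild
anti-conservativeness of a plug-in-dispersion Wald test without
shrinkage at n = 10 per group), oracle |Δz| ≈ 1e-5, TPM column-sum error
≈ 1e-15.

## Known limitations

* No dispersion or fold-change shrinkage: at small n the per-feature MoM
  dispersion is noisy, making the Wald test mildly anti-conservative;
  downstream TPM gates absorb most of the resulting borderline calls, but
  the engine is not a drop-in numerical replacement for shrinkage-based
  DE packages (rank agreement with one is high — Spearman ρ ≈ 0.995 in
  the cross-check test — numeric parity is a non-goal).
* Two-group contrasts only; no covariates, no likelihood-ratio tests.
* Transcript-level testing ignores read-assignment uncertainty between
  isoforms of a gene.
* The published stage counts and candidate identities of the original
  clinical analysis depend on protected patient data, a GTEx snapshot and
  versioned annotation databases, and are not reproducible from this
  package; verification is property-based on the synthetic cohort instead.
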