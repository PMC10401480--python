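# surfnom

Nomination of tumor-specific **cell-surface therapeutic targets** from bulk
RNA-seq count data, built for the neuroendocrine prostate cancer (NEPC)
setting.

NEPC is an aggressive, androgen-receptor–indifferent prostate cancer subtype
with no effective targeted therapy. Surface proteins specifically
overexpressed by NEPC cells — and quiet in benign prostate, localized
adenocarcinoma (PCa), castration-resistant adenocarcinoma (CRPC), and normal
tissues — are the target space for antibody-based modalities (ADCs, CAR-T,
bispecific engagers) and for molecular imaging. `surfnom` implements the
screening pipeline that nominates such targets from a four-group cohort of
raw count matrices, at both gene and transcript-isoform resolution, together
with a synthetic-cohort generator so the whole pipeline is testable without
protected patient data.

## The method

**Quantification.** Counts are converted to TPM
(`TPM_ij = (k_ij / ℓ_i) / Σ_i (k_ij / ℓ_i) × 10⁶`) and FPKM
(`k_ij · 10⁹ / (ℓ_i · N_j)`), with ℓ the annotated feature length.

**Differential expression.** A self-contained two-group negative-binomial
Wald engine (`Var = μ + αμ²`): median-of-ratios size factors `s_j`,
per-feature method-of-moments dispersion α̂ pooled within groups, per-group
mean fit by Newton iteration on `β = ln μ` with α fixed, and a Wald test on
`log2FC = (β_num − β_den)/ln 2` with the SE from the Fisher information.
P-values are Benjamini–Hochberg adjusted within each contrast. This is a
deliberately simplified engine in the style of the classic count-based DE
tools — no dispersion shrinkage and no fold-change moderation.

**The nomination cascade.** Five ordered stages, each recorded in a filter
trace with per-feature drop reasons:

| stage | rule (defaults) |
|---|---|
| 1 NEPC vs benign | padj < 0.05 and FC ≥ 2.0; drop if benign median TPM > 1 or NEPC median TPM < 1 |
| 2 NEPC vs PCa | padj < 0.1 and FC ≥ 1.5; analogous presence rule vs PCa |
| 3 surfaceome | keep genes in the union of surface annotation sources (CD nomenclature, CSPA, GO:0034220 / GO:0055085 / GO:0016020) |
| 4 tissue breadth | drop if median TPM > 3.0 in ≥ 5 normal tissues (GTEx-style median matrix) |
| 5 NEPC vs CRPC | padj < 0.1 and FC ≥ 1.5 |

The padj cut is strict (`<`), the fold-change cut inclusive (`≥`), and the
gates act on the *signed* log2FC (overexpression in NEPC). The isoform
branch runs the same stages on transcript counts, inherits surface
membership from the parent gene, and flags **isoform-specific** hits whose
parent gene was not itself nominated — the signature of an isoform switch
such as an NEPC-exclusive exon-inclusion variant.

## Worked example

Generate a synthetic cohort (2,000 genes; 20/20/20/12 benign/PCa/CRPC/NEPC
samples; 10 planted true targets plus 10 decoys per failure mode) and run
the gene cascade:

```bash
nominate simulate --seed 7 --out-dir demo/sim
nominate nominate-genes \
  --counts demo/sim/counts.tsv --lengths demo/sim/lengths.tsv \
  --design demo/sim/design.tsv \
  --surface-list demo/sim/surface_cd.txt --surface-list demo/sim/surface_cspa.txt \
  --go-assoc demo/sim/go_associations.tsv \
  --go-terms GO:0034220 --go-terms GO:0055085 --go-terms GO:0016020 \
  --gtex-medians demo/sim/gtex_medians.tsv --out-dir demo/genes
```

which prints `nominated 10 gene candidate(s); outputs in demo/genes` and
writes `candidates.tsv`, `trace.tsv`, `funnel.tsv`, `run_metadata.json`.
The funnel shows each stage doing its designed job:

```
stage_index  stage           n_in  n_out  top_reasons
1            nepc_vs_benign  2000     40  padj:1941;benign_tpm_high:10;log2fc:9
2            nepc_vs_pca       40     40
3            surfaceome        40     30  not_surface:10
4            gtex_breadth      30     20  broad_tissue:10
5            nepc_vs_crpc      20     10  padj:10
```

Reading it: of 2,000 genes, 40 survive the benign contrast (the 1,941
`padj` drops are background genes with no NEPC effect; the 10
`benign_tpm_high` drops are planted benign-leaky decoys); the surfaceome
stage removes the 10 non-surface decoys, the tissue-breadth stage the 10
broadly expressed decoys, and the CRPC contrast the 10 CRPC-shared decoys —
leaving exactly the 10 planted NEPC-specific surface genes. The top
candidate row in `candidates.tsv`:

```
rank  feature_id  log2fc_vs_benign  padj_vs_benign  tpm_benign  tpm_nepc
1     G0003       3.17              4.8e-14         0.33        2.88
```

i.e. an ~9-fold NEPC/benign ratio at 2.9 median NEPC TPM and 0.33 benign
TPM — present in NEPC, absent everywhere else. The isoform branch is run
analogously with `nominate nominate-isoforms --tx2gene ...
--gene-candidates demo/genes/candidates.tsv`; switch transcripts appear
with `isoform_specific = True`.

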