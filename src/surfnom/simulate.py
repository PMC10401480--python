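"""Synthetic prostate-cohort generator with planted nomination truth.

Generates everything the cascade consumes — gene and transcript count
matrices, feature lengths, a four-group cohort design, a GTEx-style
tissue-median matrix, surface-annotation files, and a ground-truth table
— entirely from a single seed.

Counts are negative binomial, ``Var = mu + alpha * mu**2``, with
per-sample size factors drawn log-uniform in ``[0.5, 2]``.  Background
genes share one log-normal baseline mean across all groups.  Planted
classes are parameterized in TPM units (the unit the cascade's presence
and tissue filters are stated in) and converted to count means through
the cohort's expected transcript-rate pool, so each class realizes a
designed pass/fail outcome at a known cascade stage:

``true_target``
    surface genes expressed only in NEPC (fold change 8 over every other
    group) and quiet in all normal tissues — the genes the cascade must
    nominate.
``crpc_shared_decoy``
    equally high in NEPC and CRPC; must die at the NEPC-vs-CRPC stage.
``nonsurface_nepc_decoy``
    the NEPC-specific profile without any surface annotation; dies at the
    surfaceome stage.
``broad_tissue_decoy``
    NEPC-specific surface genes whose tissue medians exceed 3 TPM in more
    than five tissues; die at the tissue-breadth stage.
``benign_leaky_decoy``
    strongly NEPC-overexpressed but above 1 TPM in benign prostate; die
    at the first presence gate.
``isoform_switch_gene``
    genes with group-invariant total output whose minor isoform (10% of
    transcripts outside NEPC) becomes the major one (90%) in NEPC — the
    isoform cascade's positive control; the parent gene itself passes no
    DE gate.

Tissue medians are generated directly (the cascade consumes only
medians), not via simulated tissue samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

SOURCE_IDS = ("CD", "CSPA", "GO:0034220", "GO:0055085", "GO:0016020")
GO_SOURCE_IDS = ("GO:0034220", "GO:0055085", "GO:0016020")


def _default_group_sizes() -> dict:
    # scaled-down echo of a 66/68/72/27 clinical cohort
    return {"benign": 20, "pca": 20, "crpc": 20, "nepc": 12}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults are the reference conditions."""

    n_genes: int = 2000
    group_sizes: dict = field(default_factory=_default_group_sizes)
    n_tissues: int = 30
    dispersion: float = 0.2
    baseline_log_mean: float = float(np.log(2500.0))
    baseline_log_sd: float = 1.0
    n_true_targets: int = 10
    n_crpc_shared: int = 10
    n_nonsurface: int = 10
    n_broad_tissue: int = 10
    n_benign_leaky: int = 10
    n_isoform_switch: int = 10
    target_fc: float = 8.0
    low_tpm: float = 0.4
    leaky_benign_tpm: float = 3.0
    broad_tissue_tpm: float = 6.0
    n_broad_tissues: int = 8
    switch_gene_tpm: float = 6.0
    switch_minor_fraction: float = 0.1
    length_range: tuple = (500, 5000)
    planted_length: int = 2000
    size_factor_range: tuple = (0.5, 2.0)
    tissue_log_noise_sd: float = 0.1
    seed: int = 0

    @property
    def n_planted(self) -> int:
        return (self.n_true_targets + self.n_crpc_shared + self.n_nonsurface
                + self.n_broad_tissue + self.n_benign_leaky
                + self.n_isoform_switch)

    def __post_init__(self):
        if self.n_planted > self.n_genes:
            raise ValidationError(
                f"planted class counts ({self.n_planted}) exceed n_genes "
                f"({self.n_genes})"
            )
        if self.target_fc <= 0 or self.dispersion < 0:
            raise ValidationError("effect sizes and dispersion must be positive")
        if self.n_planted and set(self.group_sizes) != {
            "benign", "pca", "crpc", "nepc"
        }:
            raise ValidationError(
                "planted classes require the benign/pca/crpc/nepc groups"
            )
        if not 0 < self.switch_minor_fraction < 0.5:
            raise ValidationError("switch_minor_fraction must be in (0, 0.5)")

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["group_sizes"] = dict(d["group_sizes"])
        d["length_range"] = list(d["length_range"])
        d["size_factor_range"] = list(d["size_factor_range"])
        return d


_CLASS_ORDER = (
    "true_target",
    "crpc_shared_decoy",
    "nonsurface_nepc_decoy",
    "broad_tissue_decoy",
    "benign_leaky_decoy",
    "isoform_switch_gene",
)

_EXPECTED = {
    # class -> (outcome, stage, reason); "" = unconstrained
    "true_target": ("nominated", "", ""),
    "crpc_shared_decoy": ("dropped", "nepc_vs_crpc", ""),
    "nonsurface_nepc_decoy": ("dropped", "surfaceome", "not_surface"),
    "broad_tissue_decoy": ("dropped", "gtex_breadth", "broad_tissue"),
    "benign_leaky_decoy": ("dropped", "nepc_vs_benign", "benign_tpm_high"),
    "isoform_switch_gene": ("dropped", "nepc_vs_benign", ""),
    "background": ("dropped", "nepc_vs_benign", ""),
}


@dataclass
class SimulatedCohort:
    config: SimConfig
    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.Series
    tissue_medians: pd.DataFrame
    annotations: dict            # source_id -> sorted list of gene ids
    truth: pd.DataFrame
    gene_means: pd.DataFrame     # planted/background NB means per group
    size_factors: pd.Series

    def write(self, outdir) -> None:
        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_counts(self.counts, outdir / "counts.tsv")
        sio.write_lengths(self.lengths, outdir / "lengths.tsv")
        sio.write_design(self.design, outdir / "design.tsv")
        sio.write_matrix(self.tissue_medians, outdir / "gtex_medians.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        for sid, fname in (("CD", "surface_cd.txt"), ("CSPA", "surface_cspa.txt")):
            (outdir / fname).write_text(
                "\n".join(self.annotations[sid]) + "\n"
                if self.annotations[sid] else ""
            )
        rows = [
            f"{g}\t{term}"
            for term in GO_SOURCE_IDS
            for g in self.annotations[term]
        ]
        (outdir / "go_associations.tsv").write_text(
            "\n".join(rows) + ("\n" if rows else "")
        )
        (outdir / "sim_metadata.json").write_text(
            json.dumps({"config": self.config.to_dict()}, indent=2) + "\n"
        )


@dataclass
class SimulatedIsoforms:
    tx_counts: pd.DataFrame
    tx_lengths: pd.Series
    tx2gene: pd.Series
    tx_medians: pd.DataFrame
    truth: pd.DataFrame

    def write(self, outdir) -> None:
        from . import io as sio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        sio.write_counts(self.tx_counts, outdir / "tx_counts.tsv")
        sio.write_lengths(self.tx_lengths, outdir / "tx_lengths.tsv")
        self.tx2gene.rename("gene_id").rename_axis("transcript_id").to_csv(
            outdir / "tx2gene.tsv", sep="\t"
        )
        sio.write_matrix(self.tx_medians, outdir / "tx_medians.tsv")
        self.truth.to_csv(outdir / "tx_truth.tsv", sep="\t", index=False)


def _rngs(seed: int) -> list:
    # fixed stream layout: 0 lengths/baseline, 1 size factors, 2 counts,
    # 3 tissue noise, 4 isoform thinning
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(5)]


def _class_labels(cfg: SimConfig) -> np.ndarray:
    labels = np.array(["background"] * cfg.n_genes, dtype=object)
    counts = (
        cfg.n_true_targets, cfg.n_crpc_shared, cfg.n_nonsurface,
        cfg.n_broad_tissue, cfg.n_benign_leaky, cfg.n_isoform_switch,
    )
    pos = 0
    for cls, n in zip(_CLASS_ORDER, counts):
        labels[pos:pos + n] = cls
        pos += n
    return labels


def _tpm_profiles(cfg: SimConfig) -> dict:
    """Designed per-class TPM by group (benign, pca, crpc, nepc)."""
    lo, fc = cfg.low_tpm, cfg.target_fc
    hi = lo * fc
    sw = cfg.switch_gene_tpm
    return {
        "true_target": {"benign": lo, "pca": lo, "crpc": lo, "nepc": hi},
        "crpc_shared_decoy": {"benign": lo, "pca": lo, "crpc": hi, "nepc": hi},
        "nonsurface_nepc_decoy": {"benign": lo, "pca": lo, "crpc": lo, "nepc": hi},
        "broad_tissue_decoy": {"benign": lo, "pca": lo, "crpc": lo, "nepc": hi},
        "benign_leaky_decoy": {
            "benign": cfg.leaky_benign_tpm, "pca": lo, "crpc": lo,
            "nepc": cfg.leaky_benign_tpm * fc,
        },
        "isoform_switch_gene": {"benign": sw, "pca": sw, "crpc": sw, "nepc": sw},
    }


def simulate_cohort(config: SimConfig = SimConfig()) -> SimulatedCohort:
    """Draw one full synthetic cohort; byte-identical given the seed."""
    cfg = config
    rng_base, rng_sf, rng_counts, rng_tissue, _ = _rngs(cfg.seed)

    gene_ids = pd.Index(
        [f"G{i:04d}" for i in range(cfg.n_genes)], name="feature_id"
    )
    labels = _class_labels(cfg)
    planted = labels != "background"

    lo, hi = cfg.length_range
    lengths = rng_base.integers(lo, hi + 1, size=cfg.n_genes).astype(int)
    lengths[planted] = cfg.planted_length
    baseline = rng_base.lognormal(
        cfg.baseline_log_mean, cfg.baseline_log_sd, size=cfg.n_genes
    )

    # expected transcript-rate pool of the background; converts designed
    # TPM levels into count means: mu = tpm * 1e-6 * rate_pool * length
    rate_pool = float((baseline[~planted] / lengths[~planted]).sum())
    per_tpm = 1e-6 * rate_pool * cfg.planted_length

    groups = list(cfg.group_sizes)
    mu = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(groups))),
        index=gene_ids, columns=groups,
    )
    profiles = _tpm_profiles(cfg)
    for i, cls in enumerate(labels):
        if cls != "background":
            for g, tpm in profiles[cls].items():
                mu.iloc[i, mu.columns.get_loc(g)] = tpm * per_tpm

    sample_ids, sample_groups = [], []
    for g in groups:
        n = cfg.group_sizes[g]
        if n < 2:
            raise ValidationError(f"group '{g}' needs >= 2 samples")
        sample_ids += [f"{g}_{k:02d}" for k in range(n)]
        sample_groups += [g] * n
    design = pd.Series(
        sample_groups, index=pd.Index(sample_ids, name="sample_id"), name="group"
    )

    lo_sf, hi_sf = cfg.size_factor_range
    sf = np.exp(rng_sf.uniform(np.log(lo_sf), np.log(hi_sf), size=len(sample_ids)))
    size_factors = pd.Series(sf, index=design.index, name="size_factor")

    mean_mat = mu.loc[:, design.to_numpy()].to_numpy() * sf[None, :]
    alpha = cfg.dispersion
    if alpha > 0:
        r = 1.0 / alpha
        p = r / (r + mean_mat)
        counts = rng_counts.negative_binomial(r, p)
    else:
        counts = rng_counts.poisson(mean_mat)
    counts = pd.DataFrame(counts, index=gene_ids, columns=design.index)

    # tissue medians: background genes mirror their baseline TPM; planted
    # classes realize their designed tissue profile
    tissue_ids = [f"tissue_{t:02d}" for t in range(cfg.n_tissues)]
    base_tpm = baseline / lengths / (rate_pool + 1e-300) * 1e6
    med = np.tile(base_tpm[:, None], (1, cfg.n_tissues))
    for i, cls in enumerate(labels):
        if cls == "background":
            continue
        med[i, :] = cfg.low_tpm
        if cls == "broad_tissue_decoy":
            med[i, : cfg.n_broad_tissues] = cfg.broad_tissue_tpm
        elif cls == "isoform_switch_gene":
            med[i, :] = cfg.switch_gene_tpm
    med = med * rng_tissue.lognormal(0.0, cfg.tissue_log_noise_sd, size=med.shape)
    tissue_medians = pd.DataFrame(med, index=gene_ids, columns=tissue_ids)

    # surface annotation: every planted class except the non-surface decoys,
    # spread round-robin over the five sources with periodic double tagging
    surface_classes = {
        "true_target", "crpc_shared_decoy", "broad_tissue_decoy",
        "benign_leaky_decoy", "isoform_switch_gene",
    }
    annotations: dict[str, list] = {sid: [] for sid in SOURCE_IDS}
    surface_genes = [g for g, c in zip(gene_ids, labels) if c in surface_classes]
    for k, g in enumerate(surface_genes):
        annotations[SOURCE_IDS[k % 5]].append(g)
        if k % 3 == 0:
            annotations[SOURCE_IDS[(k + 1) % 5]].append(g)
    annotations = {sid: sorted(v) for sid, v in annotations.items()}

    truth = pd.DataFrame(
        {
            "feature_id": gene_ids,
            "class": labels,
            "expected_outcome": [_EXPECTED[c][0] for c in labels],
            "expected_stage": [_EXPECTED[c][1] for c in labels],
            "expected_reason": [_EXPECTED[c][2] for c in labels],
        }
    )

    return SimulatedCohort(
        config=cfg,
        counts=counts,
        lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
        design=design,
        tissue_medians=tissue_medians,
        annotations=annotations,
        truth=truth,
        gene_means=mu,
        size_factors=size_factors,
    )


def simulate_isoforms(
    config: SimConfig = SimConfig(),
    cohort: SimulatedCohort | None = None,
) -> SimulatedIsoforms:
    """Transcript-level matrix consistent with the gene-level cohort.

    Every gene contributes one isoform carrying its full counts; each
    isoform-switch gene contributes two, split by per-sample binomial
    thinning of the gene counts (which preserves the NB dispersion), with
    the switch isoform taking ``switch_minor_fraction`` of transcripts
    outside NEPC and ``1 - switch_minor_fraction`` inside NEPC.  Isoform
    counts therefore sum exactly to the parent gene's counts.
    """
    cfg = config
    if cfg.n_isoform_switch <= 0:
        raise ValidationError("simulate_isoforms needs n_isoform_switch > 0")
    if cohort is None:
        cohort = simulate_cohort(cfg)
    rng_thin = _rngs(cfg.seed)[4]

    labels = cohort.truth.set_index("feature_id")["class"]
    switch_genes = labels.index[labels == "isoform_switch_gene"]
    is_nepc = (cohort.design == "nepc").to_numpy()
    frac_switch = np.where(is_nepc, 1.0 - cfg.switch_minor_fraction,
                           cfg.switch_minor_fraction)

    tx_rows, tx_ids, tx_genes, tx_len = [], [], [], []
    gene_truth = cohort.truth.set_index("feature_id")
    truth_rows = []
    med_rows, med_ids = [], []
    for g in cohort.counts.index:
        k = cohort.counts.loc[g].to_numpy()
        gmed = cohort.tissue_medians.loc[g].to_numpy()
        glen = int(cohort.lengths.loc[g])
        info = gene_truth.loc[g]
        if g in set(switch_genes):
            k2 = rng_thin.binomial(k, frac_switch)
            k1 = k - k2
            for suffix, kk, medscale, row in (
                ("1", k1, 1.0 - cfg.switch_minor_fraction,
                 ("isoform_major_transcript", "dropped", "nepc_vs_benign", "")),
                ("2", k2, cfg.switch_minor_fraction,
                 ("isoform_switch_transcript", "nominated", "", "")),
            ):
                tid = f"{g}.{suffix}"
                tx_ids.append(tid)
                tx_genes.append(g)
                tx_rows.append(kk)
                tx_len.append(glen)
                med_ids.append(tid)
                med_rows.append(gmed * medscale)
                truth_rows.append((tid, g) + row)
        else:
            tid = f"{g}.1"
            tx_ids.append(tid)
            tx_genes.append(g)
            tx_rows.append(k)
            tx_len.append(glen)
            med_ids.append(tid)
            med_rows.append(gmed)
            truth_rows.append(
                (tid, g, info["class"], info["expected_outcome"],
                 info["expected_stage"], info["expected_reason"])
            )

    tx_index = pd.Index(tx_ids, name="feature_id")
    tx_counts = pd.DataFrame(
        np.vstack(tx_rows), index=tx_index, columns=cohort.counts.columns
    )
    tx_medians = pd.DataFrame(
        np.vstack(med_rows), index=pd.Index(med_ids, name="feature_id"),
        columns=cohort.tissue_medians.columns,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["feature_id", "gene_id", "class", "expected_outcome",
                 "expected_stage", "expected_reason"],
    )
    return SimulatedIsoforms(
        tx_counts=tx_counts,
        tx_lengths=pd.Series(tx_len, index=tx_index, name="length_bp"),
        tx2gene=pd.Series(tx_genes, index=tx_index, name="gene_id"),
        tx_medians=tx_medians,
        truth=truth,
    )
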