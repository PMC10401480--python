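"""The sequential target-nomination cascade.

Starting from a raw count matrix of a four-group prostate cohort (benign,
localized adenocarcinoma "pca", castration-resistant "crpc", and
neuroendocrine "nepc"), candidates specifically overexpressed in NEPC are
nominated through five ordered stages:

1. ``nepc_vs_benign`` — NB Wald DE gate (padj < 0.05, fold change >= 2.0)
   plus a presence gate: drop if benign median TPM > 1 or NEPC median
   TPM < 1.
2. ``nepc_vs_pca``    — DE gate (padj < 0.1, FC >= 1.5) plus the analogous
   presence gate against localized adenocarcinoma.
3. ``surfaceome``     — restrict to genes in the surface-protein catalog.
4. ``gtex_breadth``   — drop features whose median TPM exceeds 3.0 in five
   or more normal tissues of a GTEx-style tissue-median matrix.
5. ``nepc_vs_crpc``   — DE gate (padj < 0.1, FC >= 1.5).

Boundary conventions follow the stated rules exactly: the padj cut is a
strict "less than", the fold-change cut is inclusive ("greater than or
equal to"), and the tissue-breadth cut drops at "five or more" tissues.
The DE gate is applied to the signed log2 fold change (overexpression in
NEPC), not its absolute value.

Every stage is recorded in a :class:`FilterTrace` with parameters, the
surviving set, and a per-dropped-feature reason code.  When a feature
fails several rules of one stage, the recorded reason follows the fixed
precedence padj -> log2fc -> <group>_tpm_high -> nepc_tpm_low.

The isoform branch runs the identical five stages on transcript-level
counts, decides surfaceome membership through the parent gene, and flags
isoform-specific hits — transcripts nominated while their parent gene was
not (an isoform-switch signature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import diffexpr, quantify
from ._validation import check_count_matrix, check_design, require_group
from .errors import MissingMappingError, ValidationError
from .surfaceome import SurfaceCatalog, warn_unannotated

GROUPS = ("benign", "pca", "crpc", "nepc")
STAGE_NAMES = (
    "nepc_vs_benign",
    "nepc_vs_pca",
    "surfaceome",
    "gtex_breadth",
    "nepc_vs_crpc",
)


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds of the five-stage cascade (all overridable)."""

    benign_padj: float = 0.05
    benign_fc: float = 2.0
    pca_padj: float = 0.1
    pca_fc: float = 1.5
    crpc_padj: float = 0.1
    crpc_fc: float = 1.5
    presence_tpm: float = 1.0
    gtex_median_tpm: float = 3.0
    gtex_max_tissues: int = 5
    presence_statistic: str = "median"
    abundance_unit: str = "TPM"
    lfc_cap: float = 10.0
    exclude_tissues: tuple = ()

    def __post_init__(self):
        for f in (
            "benign_padj", "benign_fc", "pca_padj", "pca_fc",
            "crpc_padj", "crpc_fc", "presence_tpm", "gtex_median_tpm",
        ):
            if getattr(self, f) <= 0:
                raise ValidationError(f"{f} must be positive")
        if not (isinstance(self.gtex_max_tissues, (int, np.integer))
                and self.gtex_max_tissues > 0):
            raise ValidationError("gtex_max_tissues must be a positive integer")
        if self.presence_statistic not in ("median", "mean"):
            raise ValidationError("presence_statistic must be median or mean")
        if self.abundance_unit not in ("TPM", "FPKM"):
            raise ValidationError("abundance_unit must be TPM or FPKM")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CascadeConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(mapping)
        if "exclude_tissues" in kwargs:
            kwargs["exclude_tissues"] = tuple(kwargs["exclude_tissues"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["exclude_tissues"] = list(d["exclude_tissues"])
        return d

    def replace(self, **kwargs) -> "CascadeConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class StageRecord:
    name: str
    params: dict
    n_in: int
    n_out: int
    survivors: tuple      # sorted feature ids
    dropped: dict         # feature id -> reason code, sorted by id


class FilterTrace:
    """Ordered record of the cascade stages with chain validation."""

    def __init__(self) -> None:
        self.stages: list[StageRecord] = []

    def add(
        self,
        name: str,
        params: Mapping,
        incoming: Iterable[str],
        survivors: Iterable[str],
        reasons: Mapping[str, str],
    ) -> None:
        incoming = set(incoming)
        surv = set(survivors)
        if not surv <= incoming:
            raise ValidationError(f"stage {name}: survivors not a subset of input")
        if self.stages and incoming != set(self.stages[-1].survivors):
            raise ValidationError(
                f"stage {name}: input does not equal previous stage output"
            )
        dropped = {f: reasons[f] for f in sorted(incoming - surv)}
        self.stages.append(
            StageRecord(
                name=name,
                params=dict(params),
                n_in=len(incoming),
                n_out=len(surv),
                survivors=tuple(sorted(surv)),
                dropped=dropped,
            )
        )

    @property
    def final_survivors(self) -> tuple:
        return self.stages[-1].survivors if self.stages else ()

    def to_frame(self) -> pd.DataFrame:
        """One row per feature per stage with status and reason."""
        rows = []
        for i, st in enumerate(self.stages, 1):
            for f in st.survivors:
                rows.append((i, st.name, f, "kept", ""))
            for f, reason in st.dropped.items():
                rows.append((i, st.name, f, "dropped", reason))
        return pd.DataFrame(
            rows, columns=["stage_index", "stage", "feature_id", "status", "reason"]
        )

    def funnel(self) -> pd.DataFrame:
        """One row per stage: name, params, n_in, n_out, top drop reasons."""
        rows = []
        for i, st in enumerate(self.stages, 1):
            counts = pd.Series(list(st.dropped.values()), dtype=object).value_counts()
            top = ";".join(f"{r}:{n}" for r, n in counts.head(3).items())
            rows.append(
                (i, st.name, json.dumps(st.params, sort_keys=True, default=str),
                 st.n_in, st.n_out, top)
            )
        return pd.DataFrame(
            rows,
            columns=["stage_index", "stage", "params", "n_in", "n_out", "top_reasons"],
        )


# ---------------------------------------------------------------------------
# individual gates


def _de_gate(results: pd.DataFrame, padj_max: float, fc_min: float, features):
    """DE gate with reasons; strict '<' on padj, inclusive '>=' on FC."""
    lfc_min = np.log2(fc_min)
    kept, reasons = set(), {}
    padj = results["padj"]
    lfc = results["log2fc"]
    for f in features:
        if not padj.loc[f] < padj_max:
            reasons[f] = "padj"
        elif not lfc.loc[f] >= lfc_min:
            reasons[f] = "log2fc"
        else:
            kept.add(f)
    return kept, reasons


def de_gate(results: pd.DataFrame, padj_max: float, fc_min: float) -> set:
    """Features with ``padj < padj_max`` and ``log2fc >= log2(fc_min)``."""
    kept, _ = _de_gate(results, padj_max, fc_min, results.index)
    return kept


def _presence_gate(
    summary_ref: pd.Series,
    summary_nepc: pd.Series,
    threshold: float,
    features,
    ref_label: str,
):
    kept, reasons = set(), {}
    for f in features:
        if summary_ref.loc[f] > threshold:
            reasons[f] = f"{ref_label}_tpm_high"
        elif summary_nepc.loc[f] < threshold:
            reasons[f] = "nepc_tpm_low"
        else:
            kept.add(f)
    return kept, reasons


def presence_gate(
    abund: pd.DataFrame,
    design: pd.Series,
    features: Iterable[str],
    reference_group: str = "benign",
    presence_tpm: float = 1.0,
    statistic: str = "median",
) -> set:
    """Drop features abundant in the reference group or absent in NEPC.

    A feature is dropped when its summary abundance in the reference group
    exceeds *presence_tpm* OR its NEPC summary is below *presence_tpm*.
    """
    ref = quantify.group_summary(abund, design, reference_group, statistic)
    nepc = quantify.group_summary(abund, design, "nepc", statistic)
    kept, _ = _presence_gate(ref, nepc, presence_tpm, features, reference_group)
    return kept


def _gtex_breadth(medians: pd.DataFrame, config: CascadeConfig) -> pd.Series:
    cols = [c for c in medians.columns if c not in set(config.exclude_tissues)]
    return (medians[cols] > config.gtex_median_tpm).sum(axis=1)


def gtex_breadth_gate(
    medians: pd.DataFrame,
    features: Iterable[str],
    config: CascadeConfig,
) -> set:
    """Drop features with median TPM above the cut in too many tissues.

    A feature is dropped iff the number of tissues with median TPM
    strictly above ``config.gtex_median_tpm`` is >= ``config.gtex_max_tissues``.
    Features missing from the matrix count as absent everywhere.
    """
    kept, _ = _gtex_breadth_gate(medians, features, config)
    return kept


def _gtex_breadth_gate(medians, features, config):
    import logging

    features = list(features)
    missing = [f for f in features if f not in medians.index]
    if missing:
        logging.getLogger(__name__).warning(
            "%d feature(s) missing from the tissue-median matrix; "
            "treated as absent in all tissues", len(missing),
        )
    present = [f for f in features if f in medians.index]
    breadth = pd.Series(0, index=pd.Index(features, name="feature_id"), dtype=int)
    if present:
        breadth.loc[present] = _gtex_breadth_for(medians, present, config)
    kept, reasons = set(), {}
    for f in features:
        if breadth.loc[f] >= config.gtex_max_tissues:
            reasons[f] = "broad_tissue"
        else:
            kept.add(f)
    return kept, reasons


def _gtex_breadth_for(medians, features, config):
    return _gtex_breadth(medians.loc[features], config)


# ---------------------------------------------------------------------------
# full cascades


def _check_groups(design: pd.Series) -> None:
    for g in GROUPS:
        require_group(design, g)


def _abundance(counts, lengths, config):
    if config.abundance_unit == "TPM":
        return quantify.compute_tpm(counts, lengths)
    return quantify.compute_fpkm(counts, lengths)


def _run_cascade_core(counts, lengths, design, in_catalog, medians, config):
    """Shared five-stage engine; `in_catalog` maps feature id -> bool."""
    check_count_matrix(counts)
    design = check_design(design, counts.columns)
    _check_groups(design)

    abund = _abundance(counts, lengths, config)
    stat = config.presence_statistic
    summaries = {
        g: quantify.group_summary(abund, design, g, stat) for g in GROUPS
    }

    size_factors = diffexpr.estimate_size_factors(counts)
    dispersions = diffexpr.estimate_dispersions(counts, size_factors, design)
    de = {
        den: diffexpr.nb_wald_test(
            counts, size_factors, dispersions, design,
            "nepc", den, lfc_cap=config.lfc_cap,
        )
        for den in ("benign", "pca", "crpc")
    }

    trace = FilterTrace()
    current = set(counts.index)

    # stage 1: DE vs benign + presence vs benign
    kept, reasons = _de_gate(de["benign"], config.benign_padj, config.benign_fc, current)
    kept2, reasons2 = _presence_gate(
        summaries["benign"], summaries["nepc"], config.presence_tpm, kept, "benign"
    )
    reasons.update(reasons2)
    trace.add(
        "nepc_vs_benign",
        {"padj_max": config.benign_padj, "fc_min": config.benign_fc,
         "presence_tpm": config.presence_tpm, "statistic": stat},
        current, kept2, reasons,
    )
    current = kept2

    # stage 2: DE vs pca + presence vs pca
    kept, reasons = _de_gate(de["pca"], config.pca_padj, config.pca_fc, current)
    kept2, reasons2 = _presence_gate(
        summaries["pca"], summaries["nepc"], config.presence_tpm, kept, "pca"
    )
    reasons.update(reasons2)
    trace.add(
        "nepc_vs_pca",
        {"padj_max": config.pca_padj, "fc_min": config.pca_fc,
         "presence_tpm": config.presence_tpm, "statistic": stat},
        current, kept2, reasons,
    )
    current = kept2

    # stage 3: surfaceome restriction
    kept = {f for f in current if in_catalog(f)}
    reasons = {f: "not_surface" for f in current - kept}
    trace.add("surfaceome", {}, current, kept, reasons)
    current = kept

    # stage 4: tissue-breadth filter
    kept, reasons = _gtex_breadth_gate(medians, current, config)
    trace.add(
        "gtex_breadth",
        {"median_tpm": config.gtex_median_tpm,
         "max_tissues": config.gtex_max_tissues},
        current, kept, reasons,
    )
    current = kept

    # stage 5: DE vs crpc
    kept, reasons = _de_gate(de["crpc"], config.crpc_padj, config.crpc_fc, current)
    trace.add(
        "nepc_vs_crpc",
        {"padj_max": config.crpc_padj, "fc_min": config.crpc_fc},
        current, kept, reasons,
    )

    return trace, de, summaries, medians


def _candidate_frame(survivors, de, summaries, medians, config):
    idx = pd.Index(sorted(survivors), name="feature_id")
    tbl = pd.DataFrame(index=idx)
    for den in ("benign", "pca", "crpc"):
        tbl[f"log2fc_vs_{den}"] = de[den]["log2fc"].loc[idx]
        tbl[f"padj_vs_{den}"] = de[den]["padj"].loc[idx]
    for g in GROUPS:
        tbl[f"tpm_{g}"] = summaries[g].loc[idx]
    present = [f for f in idx if f in medians.index]
    breadth = pd.Series(0, index=idx, dtype=int)
    if present:
        breadth.loc[present] = _gtex_breadth(medians.loc[present], config)
    tbl["gtex_breadth"] = breadth
    # rank: NEPC-vs-CRPC log2fc desc, then NEPC-vs-benign padj asc, then id
    tbl = tbl.reset_index().sort_values(
        by=["log2fc_vs_crpc", "padj_vs_benign", "feature_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    tbl.insert(0, "rank", np.arange(1, len(tbl) + 1))
    return tbl


def run_gene_cascade(
    counts: pd.DataFrame,
    lengths: pd.Series,
    design: pd.Series,
    catalog: SurfaceCatalog,
    medians: pd.DataFrame,
    config: CascadeConfig = CascadeConfig(),
):
    """Run the five-stage gene-level cascade.

    Returns ``(candidates, trace)``: a ranked candidate table (one row per
    nominated gene, with the three contrasts' log2fc/padj, per-group
    summary TPMs, surfaceome provenance, tissue breadth, and rank) and the
    complete :class:`FilterTrace`.
    """
    warn_unannotated(catalog, counts.index)
    trace, de, summaries, medians = _run_cascade_core(
        counts, lengths, design, lambda f: f in catalog, medians, config
    )
    tbl = _candidate_frame(trace.final_survivors, de, summaries, medians, config)
    tbl["sources"] = [
        ",".join(sorted(catalog.sources_of(f))) for f in tbl["feature_id"]
    ]
    return tbl, trace


def run_isoform_cascade(
    tx_counts: pd.DataFrame,
    tx_lengths: pd.Series,
    design: pd.Series,
    tx2gene: pd.Series,
    catalog: SurfaceCatalog,
    tx_medians: pd.DataFrame,
    config: CascadeConfig = CascadeConfig(),
    gene_candidates: Iterable[str] | None = None,
):
    """Run the five-stage cascade at transcript-isoform level.

    Surfaceome membership is decided through the parent gene (``tx2gene``
    must map every transcript).  If *gene_candidates* (the gene cascade's
    nominated genes) is given, each candidate isoform is flagged
    ``isoform_specific`` when its parent gene was NOT itself nominated —
    the isoform-switch signature.
    """
    missing = tx_counts.index.difference(tx2gene.index)
    if len(missing):
        raise MissingMappingError(
            f"transcript(s) without gene mapping: {sorted(missing)[:5]}"
        )
    parent = tx2gene.loc[tx_counts.index]
    parent_of = parent.to_dict()
    trace, de, summaries, medians = _run_cascade_core(
        tx_counts, tx_lengths, design,
        lambda t: parent_of[t] in catalog, tx_medians, config,
    )
    tbl = _candidate_frame(trace.final_survivors, de, summaries, medians, config)
    tbl.insert(2, "gene_id", [parent_of[t] for t in tbl["feature_id"]])
    tbl["sources"] = [
        ",".join(sorted(catalog.sources_of(g))) for g in tbl["gene_id"]
    ]
    gene_set = set(gene_candidates) if gene_candidates is not None else set()
    tbl["isoform_specific"] = [g not in gene_set for g in tbl["gene_id"]]
    return tbl, trace
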