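"""Summary reporting: stage funnels, group-mean exports, run metadata."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from ._validation import check_design
from .cascade import FilterTrace
from .errors import ValidationError

try:  # pragma: no cover - metadata lookup
    from importlib.metadata import version as _pkg_version

    VERSION = _pkg_version("surfnom")
except Exception:  # pragma: no cover
    VERSION = "unknown"


def funnel_report(trace: FilterTrace) -> pd.DataFrame:
    """Stage-by-stage funnel: name, parameters, n_in, n_out, top reasons."""
    return trace.funnel()


def export_group_means(
    abund: pd.DataFrame,
    design: pd.Series,
    features,
    tissue_medians: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Feature x group matrix of mean abundances (heat-map input).

    Column order is benign, pca, crpc, nepc (those present in the design,
    in that canonical order, then any further groups alphabetically),
    followed by the tissue columns when a tissue-median matrix is given.
    """
    features = list(features)
    unknown = [f for f in features if f not in abund.index]
    if unknown:
        raise ValidationError(f"unknown feature(s): {unknown[:5]}")
    design = check_design(design, abund.columns)
    canonical = [g for g in ("benign", "pca", "crpc", "nepc")
                 if g in set(design)]
    extra = sorted(set(design) - set(canonical))
    out = pd.DataFrame(index=pd.Index(features, name="feature_id"))
    for g in canonical + extra:
        out[g] = abund.loc[features, design.index[design == g]].mean(axis=1)
    if tissue_medians is not None:
        for t in tissue_medians.columns:
            out[t] = tissue_medians.reindex(features)[t]
    return out


def file_checksums(paths) -> dict:
    out = {}
    for p in paths:
        p = Path(p)
        out[p.name] = hashlib.md5(p.read_bytes()).hexdigest()
    return out


def run_metadata(config: dict, inputs=(), seed=None) -> dict:
    """Everything needed to reproduce a run byte-identically."""
    return {
        "tool": "surfnom",
        "version": VERSION,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "input_checksums": file_checksums(inputs),
        "seed": seed,
    }


def write_run_metadata(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
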