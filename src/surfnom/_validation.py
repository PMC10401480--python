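"""Shared input validation for the feature x sample containers.

The in-memory containers are plain pandas objects:

* count matrix   -- ``DataFrame`` (index = feature ids, columns = sample ids,
  non-negative integers)
* feature lengths -- ``Series`` (index = feature ids, positive integers, bp)
* cohort design  -- ``Series`` (index = sample ids, values = group labels)
* abundance matrix -- ``DataFrame`` like the count matrix but real-valued,
  with ``attrs["unit"]`` set to ``"TPM"`` or ``"FPKM"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import MissingGroupError, MissingLengthError, ValidationError


def check_count_matrix(counts: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(counts, pd.DataFrame):
        raise ValidationError("count matrix must be a pandas DataFrame")
    if counts.index.has_duplicates:
        dupes = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
    if counts.columns.has_duplicates:
        dupes = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample ids: {dupes[:5]}")
    values = counts.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise ValidationError("count matrix must be numeric")
    if values.size and (values < 0).any():
        raise ValidationError("count matrix contains negative values")
    if values.size and not np.allclose(values, np.round(values)):
        raise ValidationError("count matrix contains non-integer values")
    return counts


def check_lengths(lengths: pd.Series, features: pd.Index) -> pd.Series:
    missing = features.difference(lengths.index)
    if len(missing):
        raise MissingLengthError(
            f"no length for feature(s): {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    sub = lengths.loc[features].astype(float)
    if (sub <= 0).any():
        bad = sub.index[sub <= 0].tolist()
        raise ValidationError(f"non-positive length for feature(s): {bad[:5]}")
    return sub


def check_design(design: pd.Series, samples: pd.Index) -> pd.Series:
    missing = samples.difference(design.index)
    if len(missing):
        raise ValidationError(
            f"sample(s) missing from design: {sorted(missing)[:5]}"
        )
    return design.loc[samples]


def require_group(design: pd.Series, group: str) -> pd.Index:
    """Return the sample ids of *group*, or raise naming the group."""
    mask = design == group
    if not mask.any():
        raise MissingGroupError(f"group '{group}' not present in design")
    return design.index[mask]
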