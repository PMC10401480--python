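"""Length-normalized abundance units (TPM / FPKM) and group summaries.

TPM is the rate-normalized unit: per sample, each feature's count is
divided by its length in bases to give a read rate, and rates are rescaled
to sum to one million, so a feature's TPM is its share of the sample's
transcript pool times 1e6.  FPKM normalizes each count by feature length
in kilobases and by the sample's total mapped fragments in millions.  The
two are proportional within a sample; TPM is the unit the nomination
cascade's presence and tissue-breadth filters are stated in.

Effective length is the annotated feature length; no fragment-length
correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from ._validation import check_count_matrix, check_design, check_lengths, require_group
from .errors import ValidationError

logger = logging.getLogger(__name__)

_SCALE = 1e6


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million abundance matrix.

    Per sample j: ``rate_ij = count_ij / length_i`` and
    ``TPM_ij = rate_ij / sum_i(rate_ij) * 1e6``.  Columns with no reads at
    all stay all-zero (with a logged warning) rather than dividing by zero.
    """
    check_count_matrix(counts)
    length = check_lengths(lengths, counts.index).to_numpy()
    rates = counts.to_numpy(dtype=float) / length[:, None]
    totals = rates.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample column(s) left as zero TPM: %s",
            list(counts.columns[zero_cols]),
        )
    safe = np.where(zero_cols, 1.0, totals)
    tpm = pd.DataFrame(
        rates / safe * _SCALE, index=counts.index, columns=counts.columns
    )
    tpm.attrs["unit"] = "TPM"
    return tpm


def compute_fpkm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Fragments per kilobase per million mapped reads.

    ``FPKM_ij = count_ij * 1e9 / (length_i * N_j)`` with ``N_j`` the total
    counts of sample j.
    """
    check_count_matrix(counts)
    length = check_lengths(lengths, counts.index).to_numpy()
    values = counts.to_numpy(dtype=float)
    totals = values.sum(axis=0)
    zero_cols = totals == 0
    if zero_cols.any():
        logger.warning(
            "all-zero sample column(s) left as zero FPKM: %s",
            list(counts.columns[zero_cols]),
        )
    safe = np.where(zero_cols, 1.0, totals)
    fpkm = pd.DataFrame(
        values * 1e9 / (length[:, None] * safe),
        index=counts.index,
        columns=counts.columns,
    )
    fpkm.attrs["unit"] = "FPKM"
    return fpkm


def group_summary(
    abund: pd.DataFrame,
    design: pd.Series,
    group: str,
    statistic: str = "median",
) -> pd.Series:
    """Per-feature summary (median or mean) over one group's samples.

    The even-count median is the mean of the two central order statistics.
    """
    design = check_design(design, abund.columns)
    samples = require_group(design, group)
    block = abund.loc[:, samples]
    if statistic == "median":
        out = block.median(axis=1)
    elif statistic == "mean":
        out = block.mean(axis=1)
    else:
        raise ValidationError(f"unknown summary statistic '{statistic}'")
    out.name = f"{statistic}_{group}"
    return out
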