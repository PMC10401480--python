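"""Negative-binomial Wald-test differential expression engine.

A self-contained, deliberately simple two-group NB engine in the style of
the classic count-based DE tools:

* depth normalization by median-of-ratios size factors,
* per-feature method-of-moments dispersion pooled within groups
  (no empirical-Bayes shrinkage),
* per-group NB mean fit by Newton iteration on the log mean with the
  dispersion held fixed,
* Wald test on the log2 fold change with the standard error taken from
  the expected (Fisher) information,
* Benjamini-Hochberg adjustment within the comparison.

The NB parameterization throughout is ``Var = mu + alpha * mu**2``.
Positive log2 fold change means higher expression in the *numerator*
group.  No shrinkage or moderation of fold changes is applied, and no
independent filtering of low-count features is done here: the cascade's
abundance filters play that role downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._validation import check_count_matrix, check_design, require_group
from .errors import ValidationError

LN2 = np.log(2.0)

#: Lower bound on estimated dispersions; keeps the NB fit well-defined for
#: features that look under-dispersed (Poisson-like or constant).
DISPERSION_FLOOR = 1e-8

#: |log2 fold change| cap applied when one group has zero counts.
LFC_CAP = 10.0


def estimate_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For each feature i, let ``g_i`` be the geometric mean of its counts
    across samples; the size factor of sample j is the median of
    ``count_ij / g_i`` over the reference features (those with a nonzero
    count in every sample).
    """
    check_count_matrix(counts)
    if counts.shape[1] < 2:
        raise ValidationError("size factors need at least two samples")
    values = counts.to_numpy(dtype=float)
    reference = (values > 0).all(axis=1)
    if not reference.any():
        raise ValidationError(
            "no feature has nonzero counts in every sample; cannot form the "
            "median-of-ratios reference (pseudo-reference fallback is disabled)"
        )
    ref = values[reference]
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.exp(np.log(ref) - log_geo_mean[:, None])
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersions(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    design: pd.Series,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Method-of-moments dispersion per feature, pooled within groups.

    On normalized counts ``q = count / size_factor`` the estimator is
    ``alpha = (pooled within-group variance - pooled mean) / pooled mean**2``
    clipped from below at *floor*.  The pooled within-group variance uses
    ``N - G`` denominator degrees of freedom.  Features with zero pooled
    mean get the floor.
    """
    check_count_matrix(counts)
    design = check_design(design, counts.columns)
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    if (s <= 0).any():
        raise ValidationError("size factors must be positive")
    q = counts.to_numpy(dtype=float) / s[None, :]

    n = q.shape[1]
    groups = design.to_numpy()
    labels = pd.unique(groups)
    if n - len(labels) < 1:
        raise ValidationError("need more samples than groups to pool variance")
    for lab in labels:
        if (groups == lab).sum() < 2:
            raise ValidationError(f"group '{lab}' has fewer than 2 samples")

    ss_within = np.zeros(q.shape[0])
    for lab in labels:
        block = q[:, groups == lab]
        ss_within += ((block - block.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    pooled_var = ss_within / (n - len(labels))
    pooled_mean = q.mean(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - pooled_mean) / pooled_mean**2
    alpha = np.where(pooled_mean > 0, alpha, floor)
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _fit_log_means(
    k: np.ndarray,
    s: np.ndarray,
    alpha: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-12,
) -> np.ndarray:
    """Newton fit of beta = ln(mu) per feature, dispersion fixed.

    ``k`` is features x samples, ``s`` the per-sample size factors.  The
    sample mean is ``m_j = s_j * exp(beta)``; score and observed
    information in beta are

        U(beta)  = sum_j (k_j - m_j) / (1 + alpha m_j)
        I(beta)  = sum_j m_j (1 + alpha k_j) / (1 + alpha m_j)^2

    Features with an all-zero row get beta = -inf.
    """
    totals = k.sum(axis=1)
    nonzero = totals > 0
    beta = np.full(k.shape[0], -np.inf)
    if not nonzero.any():
        return beta
    b = np.log(totals[nonzero] / s.sum())
    kk = k[nonzero]
    a = alpha[nonzero][:, None]
    for _ in range(max_iter):
        m = s[None, :] * np.exp(b)[:, None]
        denom = 1.0 + a * m
        score = ((kk - m) / denom).sum(axis=1)
        info = (m * (1.0 + a * kk) / denom**2).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-300), -3.0, 3.0)
        b = b + step
        if np.max(np.abs(step)) < tol:
            break
    beta[nonzero] = b
    return beta


def _expected_information(
    beta: np.ndarray, s: np.ndarray, alpha: np.ndarray
) -> np.ndarray:
    """Fisher information in beta: sum_j m_j / (1 + alpha m_j)."""
    m = s[None, :] * np.exp(beta)[:, None]
    return (m / (1.0 + alpha[:, None] * m)).sum(axis=1)


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersions: pd.Series,
    design: pd.Series,
    numerator_group: str,
    denominator_group: str,
    lfc_cap: float = LFC_CAP,
) -> pd.DataFrame:
    """Two-group NB Wald test, one row per feature.

    Returns a DataFrame indexed by feature id with columns ``base_mean``,
    ``log2fc``, ``se``, ``wald_p``, ``padj`` and ``flag``;
    ``attrs["numerator"]`` / ``attrs["denominator"]`` record the contrast.

    Group means are fitted by maximum likelihood with the dispersion held
    fixed; ``log2fc = log2(mu_num / mu_den)``; the SE of the difference of
    log means combines the per-group Fisher informations; the two-sided p
    comes from the standard normal.  Features with zero counts in both
    groups get ``log2fc = 0, wald_p = 1``.  When exactly one group is all
    zero the fold change is capped at ±*lfc_cap* and the Wald statistic is
    computed from the capped fit (flagged ``num_zero`` / ``den_zero``).
    """
    check_count_matrix(counts)
    design = check_design(design, counts.columns)
    num_samples = require_group(design, numerator_group)
    den_samples = require_group(design, denominator_group)
    alpha = np.maximum(
        dispersions.loc[counts.index].to_numpy(dtype=float), DISPERSION_FLOOR
    )

    k_num = counts.loc[:, num_samples].to_numpy(dtype=float)
    k_den = counts.loc[:, den_samples].to_numpy(dtype=float)
    s_num = size_factors.loc[num_samples].to_numpy(dtype=float)
    s_den = size_factors.loc[den_samples].to_numpy(dtype=float)

    beta_num = _fit_log_means(k_num, s_num, alpha)
    beta_den = _fit_log_means(k_den, s_den, alpha)

    num_zero = ~np.isfinite(beta_num)
    den_zero = ~np.isfinite(beta_den)
    both_zero = num_zero & den_zero
    flags = np.where(
        both_zero,
        "all_zero",
        np.where(num_zero, "num_zero", np.where(den_zero, "den_zero", "")),
    )

    # capped fit for one-sided-zero features
    cap_ln = lfc_cap * LN2
    beta_num = np.where(num_zero & ~both_zero, beta_den - cap_ln, beta_num)
    beta_den = np.where(den_zero & ~both_zero, beta_num - cap_ln, beta_den)
    beta_num = np.where(both_zero, 0.0, beta_num)
    beta_den = np.where(both_zero, 0.0, beta_den)

    info_num = _expected_information(beta_num, s_num, alpha)
    info_den = _expected_information(beta_den, s_den, alpha)
    var = 1.0 / info_num + 1.0 / info_den

    log2fc = (beta_num - beta_den) / LN2
    se = np.sqrt(var) / LN2
    z = log2fc / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))

    log2fc[both_zero] = 0.0
    wald_p[both_zero] = 1.0
    se[both_zero] = np.inf

    norm_all = np.hstack([k_num / s_num[None, :], k_den / s_den[None, :]])
    base_mean = norm_all.mean(axis=1)

    out = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_p": wald_p,
            "padj": bh_adjust(wald_p),
            "flag": flags,
        },
        index=counts.index,
    )
    out.index.name = "feature_id"
    out.attrs["numerator"] = numerator_group
    out.attrs["denominator"] = denominator_group
    return out


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sort ascending, take ``q_(i) = min_{j >= i} p_(j) * m / j`` clipped at
    1, and restore the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out
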