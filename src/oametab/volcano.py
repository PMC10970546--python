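"""Paired volcano-plot selection: fold change combined with a paired t-test.

For each feature, the fold change is the ratio of the later-timepoint mean
intensity over the earlier one (linear scale), and the p-value comes from a
two-sided paired t-test on log10 intensities, pairing each subject's two
samples. A feature is selected when both |log2 FC| >= log2(fc_threshold)
(i.e. FC >= 2 or FC <= 0.5 at the default) and p < p_threshold. No
multiple-testing correction is applied: selection is deliberately a raw
p < 0.05 screen feeding the multivariate model, not an inference in itself.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from oametab.io import FeatureTable, SampleSheet

__all__ = ["volcano", "impute_half_min"]


def impute_half_min(intensities: pd.DataFrame) -> pd.DataFrame:
    """Replace missing/non-positive cells by half the feature's minimum
    positive observed intensity (standard left-censoring imputation).

    Features with no positive observation at all are left as NaN.
    """
    vals = intensities.to_numpy(dtype=float).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        pos = np.where(vals > 0, vals, np.nan)
        half_min = np.nanmin(pos, axis=1) / 2.0
    fill = np.broadcast_to(half_min[:, None], vals.shape)
    mask = ~(vals > 0)
    vals[mask] = fill[mask]
    return pd.DataFrame(vals, index=intensities.index, columns=intensities.columns)


def volcano(
    table: FeatureTable,
    sheet: SampleSheet,
    t_early: str,
    t_late: str,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Paired volcano table for one timepoint comparison.

    Returns a DataFrame indexed by feature id with columns ``fc``,
    ``log2_fc``, ``p_value``, ``neg_log10_p``, ``selected``, ``degenerate``
    and ``excluded``. Degenerate features are those whose paired log10
    differences are all identical (p defined as 0 when the common
    difference is nonzero, 1 when it is zero). Excluded features had no
    positive intensity at one of the timepoints even after imputation.
    """
    pairs = sheet.pairs(t_early, t_late)
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 subject pairs, found {len(pairs)}")
    early_ids = list(pairs["early"])
    late_ids = list(pairs["late"])

    imputed = impute_half_min(table.intensities[early_ids + late_ids])
    early = imputed[early_ids].to_numpy(dtype=float)
    late = imputed[late_ids].to_numpy(dtype=float)

    excluded = np.isnan(early).any(axis=1) | np.isnan(late).any(axis=1)
    if excluded.any():
        warnings.warn(
            f"{int(excluded.sum())} feature(s) had no positive intensity and "
            "were excluded from the volcano test"
        )

    with np.errstate(invalid="ignore", divide="ignore"):
        fc = late.mean(axis=1) / early.mean(axis=1)
        log2_fc = np.log2(fc)
        diffs = np.log10(late) - np.log10(early)
        mean_d = diffs.mean(axis=1)
        sd_d = diffs.std(axis=1, ddof=1)

    n = diffs.shape[1]
    degenerate = (sd_d == 0) & ~excluded
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat = mean_d / (sd_d / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 1)
    p[degenerate] = np.where(mean_d[degenerate] != 0.0, 0.0, 1.0)
    p[excluded] = np.nan
    fc[excluded] = np.nan

    selected = (
        ~excluded
        & (np.abs(np.where(excluded, 0.0, log2_fc)) >= np.log2(fc_threshold))
        & (p < p_threshold)
    )
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(p)
    return pd.DataFrame(
        {
            "fc": fc,
            "log2_fc": log2_fc,
            "p_value": p,
            "neg_log10_p": neg_log10_p,
            "selected": selected,
            "degenerate": degenerate,
            "excluded": excluded,
        },
        index=table.features.index,
    )
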