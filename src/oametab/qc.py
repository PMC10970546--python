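"""Internal-standard evaluation/normalization and QC-pool CV filtering.

The internal standard (leucine-enkephalin in positive ESI, reserpine in
negative) is spiked into every injection at constant amount, so its area
tracks instrument response: a trend over injection order indicates drift,
and dividing each sample by its ISTD response ratio removes
injection-to-injection variability. After normalization, per-feature
coefficients of variation across the pooled-QC injections measure purely
analytical variability; features with CV% at or above the threshold
(default 30%) are removed so that surviving variation can be read as
biological.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from oametab.io import FeatureTable, SampleSheet

__all__ = ["IstdReport", "CvFilterResult", "istd_report", "normalize_to_istd", "cv_filter"]


@dataclass
class IstdReport:
    """Control chart of an internal standard over the injection sequence."""

    istd_id: str
    areas: pd.DataFrame  # columns: sample_id, injection_order, area
    slope: float  # least-squares slope of area vs injection order
    slope_p_value: float  # t-test on the slope
    cv_percent: float  # 100 * sd / mean of the areas


def istd_report(table: FeatureTable, sheet: SampleSheet, istd_id: str) -> IstdReport:
    """Evaluate the ISTD response across all injections, in order."""
    if istd_id not in table.features.index:
        raise KeyError(f"internal standard {istd_id!r} not in feature table")
    order = sheet.data.loc[table.sample_ids, "injection_order"]
    areas = pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "injection_order": order.to_numpy(),
            "area": table.intensities.loc[istd_id].to_numpy(dtype=float),
        }
    ).sort_values("injection_order", ignore_index=True)
    if len(areas) < 3:
        raise ValueError("need at least 3 injections for an ISTD report")
    if areas["area"].isna().any():
        bad = areas.loc[areas["area"].isna(), "sample_id"].iloc[0]
        raise ValueError(f"ISTD area missing in sample {bad!r}")
    x = areas["injection_order"].to_numpy(dtype=float)
    y = areas["area"].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        slope, p = 0.0, 1.0
    else:
        fit = stats.linregress(x, y)
        slope, p = float(fit.slope), float(fit.pvalue)
    cv = 100.0 * np.std(y, ddof=1) / np.mean(y) if np.mean(y) != 0 else np.inf
    return IstdReport(istd_id=istd_id, areas=areas, slope=slope,
                      slope_p_value=p, cv_percent=float(cv))


def normalize_to_istd(table: FeatureTable, sheet: SampleSheet, istd_id: str) -> FeatureTable:
    """Scale each sample by (median ISTD area) / (its ISTD area).

    The median across samples is the reference so that one aberrant
    injection cannot move every other sample. Idempotent: after one pass
    the ISTD row is constant at the median, so a second pass is a no-op.
    """
    if istd_id not in table.features.index:
        raise KeyError(f"internal standard {istd_id!r} not in feature table")
    areas = table.intensities.loc[istd_id]
    bad = areas.index[areas.isna() | (areas <= 0)]
    if len(bad):
        raise ValueError(f"ISTD area zero or missing in sample {bad[0]!r}")
    factors = areas.median() / areas
    out = table.copy()
    out.intensities = out.intensities.mul(factors, axis=1)
    return out


@dataclass
class CvFilterResult:
    """Outcome of the QC-pool CV filter."""

    cv_percent: pd.Series  # per feature; NaN when unquantifiable in QC
    retained: list[str]
    removed: list[str]
    threshold_percent: float

    def apply(self, table: FeatureTable) -> FeatureTable:
        return table.subset(self.retained)


def cv_filter(
    table: FeatureTable,
    sheet: SampleSheet,
    threshold_percent: float = 30.0,
    max_missing_fraction: float = 0.5,
) -> CvFilterResult:
    """Remove features whose QC-pool CV% is at or above the threshold.

    Conditioning QC injections are excluded; the CV uses the sample
    standard deviation (n-1). A feature missing in more than
    ``max_missing_fraction`` of the pool injections is removed as
    unquantifiable (CV% reported as NaN).
    """
    qc_ids = [s for s in sheet.qc_pool_ids if s in table.intensities.columns]
    if len(qc_ids) < 3:
        raise ValueError(f"need at least 3 QC pool injections, found {len(qc_ids)}")
    qc = table.intensities[qc_ids]
    n_obs = qc.notna().sum(axis=1)
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    cv = 100.0 * sd / mean
    unquantifiable = (n_obs < (1.0 - max_missing_fraction) * len(qc_ids)) | (mean <= 0)
    cv[unquantifiable] = np.nan
    remove = unquantifiable | (cv >= threshold_percent)
    retained = [f for f, r in zip(table.feature_ids, remove) if not r]
    removed = [f for f, r in zip(table.feature_ids, remove) if r]
    return CvFilterResult(
        cv_percent=cv,
        retained=retained,
        removed=removed,
        threshold_percent=float(threshold_percent),
    )
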