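"""A-priori histogram and geometry features of a nodule.

Computes the conventional first-line radiomics descriptors of a
CT-attenuation histogram — count-weighted moments (mean, SD, skewness,
Pearson kurtosis), interpolated quantiles (Q.50, Q.75, Q.875, IQR) — plus the
geometric predictors (log10 volume, max/min diameter ratio, consolidation
ratio), and assembles them into one feature table row per nodule.

Conventions fixed here: moments are population moments (no small-sample
correction; voxel counts are large), kurtosis is the non-excess Pearson
kurtosis (Gaussian = 3), and quantiles treat the histogram mass as uniform
within each bin (linear CDF inversion).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .cohort import AttenuationHistogram, CohortDataset, NoduleRecord

__all__ = [
    "DegenerateHistogramError",
    "HistogramMoments",
    "histogram_moments",
    "histogram_quantiles",
    "consolidation_ratio",
    "geometry_features",
    "assemble_feature_table",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_COLUMNS",
]


class DegenerateHistogramError(ValueError):
    """Histogram has zero spread; skewness and kurtosis are undefined."""


class HistogramMoments(NamedTuple):
    mean: float
    sd: float
    skewness: float
    kurtosis: float


def histogram_moments(hist: AttenuationHistogram) -> HistogramMoments:
    """Count-weighted population moments over the bin centers.

    Kurtosis is Pearson (non-excess): a Gaussian histogram gives 3.
    """
    x = hist.bin_centers
    w = hist.counts.astype(float)
    n = w.sum()
    if n < 2:
        raise ValueError("need at least 2 voxels for a standard deviation")
    mean = float(np.average(x, weights=w))
    d = x - mean
    var = float(np.average(d**2, weights=w))
    sd = np.sqrt(var)
    if sd == 0:
        raise DegenerateHistogramError("all mass in a single bin: sd = 0")
    skew = float(np.average(d**3, weights=w) / sd**3)
    kurt = float(np.average(d**4, weights=w) / sd**4)
    return HistogramMoments(mean, float(sd), skew, kurt)


def histogram_quantiles(
    hist: AttenuationHistogram, probs: Sequence[float]
) -> np.ndarray:
    """Weighted empirical quantiles with mass uniform inside each bin."""
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() <= 0 or probs.max() >= 1):
        raise ValueError("probabilities must lie strictly inside (0, 1)")
    counts = hist.counts.astype(float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    width = hist.bin_width
    left = hist.bin_centers - width / 2.0
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    targets = probs * total
    # bin k covers cumulative mass (cum[k], cum[k+1]]
    idx = np.searchsorted(cum, targets, side="left")
    idx = np.clip(idx - 1, 0, counts.size - 1)
    # skip empty bins the target may have landed on the boundary of
    while True:
        empty = counts[idx] == 0
        if not empty.any():
            break
        idx = np.where(empty, np.minimum(idx + 1, counts.size - 1), idx)
        if np.all(counts[np.clip(idx, 0, counts.size - 1)] > 0):
            break
    frac = (targets - cum[idx]) / counts[idx]
    return left[idx] + np.clip(frac, 0.0, 1.0) * width


def consolidation_ratio(max_consolidation_mm: float, max_diameter_mm: float) -> float:
    """Solid-component share of the lesion: max consolidation / max diameter."""
    if max_diameter_mm <= 0:
        raise ValueError("max diameter must be positive")
    if max_consolidation_mm < 0:
        raise ValueError("max consolidation must be non-negative")
    if max_consolidation_mm > max_diameter_mm:
        raise ValueError("max consolidation cannot exceed max diameter")
    return max_consolidation_mm / max_diameter_mm


def geometry_features(record: NoduleRecord) -> tuple[float, float]:
    """(log10 volume in mm^3, max/min diameter ratio) of a nodule."""
    if record.volume_mm3 <= 0 or record.min_diameter_mm <= 0:
        raise ValueError("volume and min diameter must be positive")
    return (
        float(np.log10(record.volume_mm3)),
        record.max_diameter_mm / record.min_diameter_mm,
    )


FEATURE_COLUMNS = [
    "nodule_id",
    "class_label",
    "pathology_subtype",
    "mean_hu",
    "sd_hu",
    "skewness_hu",
    "kurtosis_hu",
    "q50_hu",
    "q75_hu",
    "q875_hu",
    "iqr_hu",
    "consolidation_ratio",
    "log10_volume",
    "min_diameter_mm",
    "max_diameter_mm",
    "mean_diameter_mm",
    "diameter_ratio",
]


def assemble_feature_table(cohort: CohortDataset | Iterable[NoduleRecord]) -> pd.DataFrame:
    """One row of a-priori features per nodule, in a deterministic column order."""
    records = list(cohort.records if isinstance(cohort, CohortDataset) else cohort)
    ids = [r.nodule_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate nodule ids: {dup}")
    rows = []
    for rec in records:
        try:
            mom = histogram_moments(rec.histogram)
            q25, q50, q75, q875 = histogram_quantiles(
                rec.histogram, [0.25, 0.5, 0.75, 0.875]
            )
        except (ValueError, DegenerateHistogramError) as exc:
            raise type(exc)(f"nodule {rec.nodule_id}: {exc}") from exc
        log10_vol, ratio = geometry_features(rec)
        rows.append(
            {
                "nodule_id": rec.nodule_id,
                "class_label": rec.class_label,
                "pathology_subtype": rec.pathology_subtype,
                "mean_hu": mom.mean,
                "sd_hu": mom.sd,
                "skewness_hu": mom.skewness,
                "kurtosis_hu": mom.kurtosis,
                "q50_hu": float(q50),
                "q75_hu": float(q75),
                "q875_hu": float(q875),
                "iqr_hu": float(q75 - q25),
                "consolidation_ratio": consolidation_ratio(
                    rec.max_consolidation_mm, rec.max_diameter_mm
                ),
                "log10_volume": log10_vol,
                "min_diameter_mm": rec.min_diameter_mm,
                "max_diameter_mm": rec.max_diameter_mm,
                "mean_diameter_mm": rec.mean_diameter_mm,
                "diameter_ratio": ratio,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
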