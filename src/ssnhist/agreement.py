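"""Inter-reader agreement of the classification pipeline.

Two readers independently correct the nodule segmentations, so the pipeline
sees two slightly different cohorts.  Agreement of the downstream model is
quantified at the predicted-class level by Cohen's kappa and at the
predicted-probability level by the two-way random-effects, absolute-
agreement, single-measure intraclass correlation ICC(2,1).  Both carry
percentile bootstrap confidence intervals over paired subject resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .modeling import ModelSpec, MODEL_SPECS, fit_logistic

__all__ = [
    "KappaResult",
    "ICCResult",
    "AgreementResult",
    "cohens_kappa",
    "icc",
    "reader_agreement",
]


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_bootstrap: int
    degenerate: bool = False


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_pairs: int
    n_bootstrap: int
    degenerate: bool = False


def _kappa_point(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    n = a.size
    p_o = float((a == b).mean())
    p_e = 0.0
    for c in (0, 1):
        p_e += float((a == c).mean()) * float((b == c).mean())
    if p_e >= 1.0 - 1e-12:
        # both raters constant: kappa is 1 for identical vectors, undefined otherwise
        return (1.0, False) if p_o == 1.0 else (np.nan, True)
    return (p_o - p_e) / (1.0 - p_e), False


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        classes = np.unique(y)
        if classes.size > 2:
            raise ValueError("labels must be binary")
        return (y == classes[-1]).astype(int)
    y = y.astype(int)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    return y


def cohens_kappa(
    labels_a,
    labels_b,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> KappaResult:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e)."""
    a = _as_binary(labels_a)
    b = _as_binary(labels_b)
    if a.size != b.size:
        raise ValueError("label vectors must have equal length")
    kappa, degenerate = _kappa_point(a, b)
    if degenerate or n_bootstrap == 0:
        return KappaResult(kappa, kappa, kappa, a.size, 0, degenerate)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        take = rng.integers(0, a.size, size=a.size)
        k, deg = _kappa_point(a[take], b[take])
        if not deg:
            boots.append(k)
    if boots:
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(float(lo), kappa), max(float(hi), kappa)
    else:
        lo = hi = kappa
    return KappaResult(kappa, lo, hi, a.size, n_bootstrap, False)


def _icc21_point(a: np.ndarray, b: np.ndarray) -> tuple[float, bool]:
    """ICC(2,1) from the two-way mean squares with k = 2 raters."""
    n = a.size
    k = 2
    x = np.stack([a, b], axis=1)
    grand = x.mean()
    subj_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_total = float(((x - grand) ** 2).sum())
    ss_rows = k * float(((subj_means - grand) ** 2).sum())
    ss_cols = n * float(((rater_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= 1e-15 or abs(denom) < 1e-15:
        return np.nan, True
    return (msr - mse) / denom, False


def icc(
    probs_a,
    probs_b,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ICCResult:
    """Absolute-agreement single-measure ICC(2,1) between two raters."""
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    value, degenerate = _icc21_point(a, b)
    if degenerate or n_bootstrap == 0:
        return ICCResult(value, value, value, a.size, 0, degenerate)
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        take = rng.integers(0, a.size, size=a.size)
        v, deg = _icc21_point(a[take], b[take])
        if not deg:
            boots.append(v)
    if boots:
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        lo, hi = min(float(lo), value), max(float(hi), value)
    else:
        lo = hi = value
    return ICCResult(value, lo, hi, a.size, n_bootstrap, False)


@dataclass
class AgreementResult:
    kappa: KappaResult
    icc: ICCResult
    discordant_ids: tuple[str, ...]
    model: str

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "kappa": {
                "estimate": self.kappa.kappa,
                "ci": [self.kappa.ci_low, self.kappa.ci_high],
                "degenerate": self.kappa.degenerate,
            },
            "icc": {
                "estimate": self.icc.icc,
                "ci": [self.icc.ci_low, self.icc.ci_high],
                "degenerate": self.icc.degenerate,
            },
            "n_pairs": self.kappa.n_pairs,
            "discordant_nodules": list(self.discordant_ids),
        }


def reader_agreement(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    model_spec: ModelSpec | str = "model1",
    threshold: float = 0.5,
    n_bootstrap: int = 2000,
    seed: int = 0,
) -> AgreementResult:
    """Fit the same model on each reader's cohort and compare its outputs.

    Each reader's feature table yields its own fitted model; agreement is
    measured between the two vectors of predicted classes (kappa) and
    predicted probabilities (ICC) over the shared nodules.
    """
    spec = MODEL_SPECS[model_spec] if isinstance(model_spec, str) else model_spec
    if not features_a["nodule_id"].equals(features_b["nodule_id"]):
        raise ValueError("reader tables must cover the same nodules in the same order")
    fit_a = fit_logistic(features_a, spec)
    fit_b = fit_logistic(features_b, spec)
    probs_a = fit_a.predict_proba(features_a)
    probs_b = fit_b.predict_proba(features_b)
    cls_a = (probs_a >= threshold).astype(int)
    cls_b = (probs_b >= threshold).astype(int)
    kap = cohens_kappa(cls_a, cls_b, n_bootstrap=n_bootstrap, seed=seed)
    ic = icc(probs_a, probs_b, n_bootstrap=n_bootstrap, seed=seed + 1)
    discordant = tuple(features_a.loc[cls_a != cls_b, "nodule_id"])
    return AgreementResult(kappa=kap, icc=ic, discordant_ids=discordant, model=spec.name)
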