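"""Univariate screening, logistic models and their cross-validated evaluation.

The screening stage ranks every candidate predictor by its univariate
ROC-AUC (Mann-Whitney statistic with ties counted 1/2) with a Youden-optimal
operating threshold, and flags highly collinear predictor pairs via Pearson
correlation with Fisher-Z tests.  The classification stage fits multiple
logistic regressions for three fixed predictor sets and evaluates them by
repeated stratified 10-fold cross-validation (out-of-fold probabilities
pooled per repeat) plus a bootstrap optimism-corrected calibration curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import mannwhitneyu, rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ROCResult",
    "ModelSpec",
    "MODEL_SPECS",
    "CVResult",
    "CalibrationResult",
    "CorrelationScreen",
    "FittedLogistic",
    "PerfectSeparationWarning",
    "auc_mann_whitney",
    "univariate_auc",
    "correlation_screen",
    "fit_logistic",
    "repeated_kfold_cv",
    "calibration_error",
    "evaluate_models",
    "TABLE3_PREDICTORS",
    "POSITIVE_CLASS",
]

#: the invasive class is the "positive" class throughout
POSITIVE_CLASS = "T2"

#: predictors screened univariately, in feature-table order
TABLE3_PREDICTORS = [
    "fpc1",
    "sd_hu",
    "q875_hu",
    "iqr_hu",
    "q75_hu",
    "consolidation_ratio",
    "mean_hu",
    "q50_hu",
    "kurtosis_hu",
    "max_diameter_mm",
    "skewness_hu",
    "log10_volume",
    "mean_diameter_mm",
    "diameter_ratio",
    "min_diameter_mm",
    "fpc2",
]


class PerfectSeparationWarning(UserWarning):
    """The logistic likelihood is unbounded; coefficients stopped at max_iter."""


# ---------------------------------------------------------------------------
# univariate ROC screening
# ---------------------------------------------------------------------------


def _binary_labels(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "OUS":
        return (y == POSITIVE_CLASS).astype(int)
    return y.astype(int)


def auc_mann_whitney(values, labels) -> float:
    """P(X_pos > X_neg) + 1/2 P(tie), via the rank-sum statistic."""
    x = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n0 * n1))


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    best_threshold: float
    direction: str  # "greater": predict positive when value > threshold
    p_value: float
    n_bootstrap: int


def _youden_threshold(x: np.ndarray, y: np.ndarray, direction: str):
    """Maximise J = sens + spec - 1 over midpoints of adjacent distinct values."""
    distinct = np.unique(x)
    if distinct.size < 2:
        thr = np.array([distinct[0]])
    else:
        thr = (distinct[1:] + distinct[:-1]) / 2.0
    pos = x[y == 1]
    neg = x[y == 0]
    if direction == "greater":
        sens = (pos[:, None] > thr[None, :]).mean(axis=0)
        spec = (neg[:, None] <= thr[None, :]).mean(axis=0)
    else:
        sens = (pos[:, None] <= thr[None, :]).mean(axis=0)
        spec = (neg[:, None] > thr[None, :]).mean(axis=0)
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # smallest threshold wins ties
    return float(thr[best]), float(sens[best]), float(spec[best])


def univariate_auc(
    values,
    labels,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
    alpha: float = 0.05,
) -> ROCResult:
    """ROC screening of one feature: AUC, stratified-bootstrap CI, Youden point.

    The reporting direction is chosen so AUC >= 0.5 ("greater" when high
    values indicate the positive class).
    """
    x = np.asarray(values, dtype=float)
    y = _binary_labels(labels)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    auc_raw = auc_mann_whitney(x, y)
    direction = "greater" if auc_raw >= 0.5 else "less"
    auc = auc_raw if direction == "greater" else 1.0 - auc_raw
    thr, sens, spec = _youden_threshold(x, y, direction)
    p_value = float(mannwhitneyu(x[y == 1], x[y == 0], alternative="two-sided").pvalue)
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        idx_pos = np.flatnonzero(y == 1)
        idx_neg = np.flatnonzero(y == 0)
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            take = np.concatenate(
                [
                    rng.choice(idx_pos, idx_pos.size, replace=True),
                    rng.choice(idx_neg, idx_neg.size, replace=True),
                ]
            )
            a = auc_mann_whitney(x[take], y[take])
            boots[b] = a if direction == "greater" else 1.0 - a
        ci_low, ci_high = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        ci_low = min(float(ci_low), auc)
        ci_high = max(float(ci_high), auc)
    else:
        ci_low = ci_high = auc
    return ROCResult(auc, ci_low, ci_high, sens, spec, thr, direction, p_value, n_bootstrap)


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrelationScreen:
    r: pd.DataFrame
    p: pd.DataFrame
    flagged: pd.DataFrame  # columns: feature_a, feature_b, r, p, discard
    zero_variance: tuple[str, ...]


def _fisher_z_p(r: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore"):
        z = np.arctanh(np.clip(r, -1.0, 1.0)) * np.sqrt(max(n - 3, 1))
    return 2.0 * (1.0 - ndtr(np.abs(z)))


def correlation_screen(
    feature_table: pd.DataFrame,
    features: Sequence[str] | None = None,
    threshold: float = 0.9,
    auc_by_feature: dict[str, float] | None = None,
) -> CorrelationScreen:
    """Pearson correlations with Fisher-Z tests; flag near-collinear pairs.

    Pairs with |r| >= ``threshold`` are flagged; when univariate AUCs are
    supplied the lower-AUC member is marked for discarding.  Zero-variance
    columns are reported separately, never an error.
    """
    if features is None:
        features = [c for c in feature_table.columns if feature_table[c].dtype.kind == "f"]
    sub = feature_table[list(features)]
    if len(sub) < 3:
        raise ValueError("need at least 3 rows")
    sd = sub.std(ddof=0)
    zero_var = tuple(sd.index[sd == 0])
    r = sub.corr(method="pearson")
    p = pd.DataFrame(
        _fisher_z_p(r.to_numpy(), len(sub)), index=r.index, columns=r.columns
    )
    rows = []
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            rv = r.loc[a, b]
            if np.isfinite(rv) and abs(rv) >= threshold:
                discard = ""
                if auc_by_feature and a in auc_by_feature and b in auc_by_feature:
                    discard = a if auc_by_feature[a] < auc_by_feature[b] else b
                rows.append(
                    {"feature_a": a, "feature_b": b, "r": float(rv),
                     "p": float(p.loc[a, b]), "discard": discard}
                )
    flagged = pd.DataFrame(rows, columns=["feature_a", "feature_b", "r", "p", "discard"])
    return CorrelationScreen(r=r, p=p, flagged=flagged, zero_variance=zero_var)


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    name: str
    predictors: tuple[str, ...]


MODEL_SPECS = {
    "model1": ModelSpec("model1", ("q875_hu", "iqr_hu", "log10_volume", "diameter_ratio")),
    "model2": ModelSpec("model2", ("fpc1", "log10_volume", "diameter_ratio")),
    "model3": ModelSpec("model3", ("fpc1", "fpc2", "log10_volume")),
}


@dataclass
class FittedLogistic:
    spec: ModelSpec
    coef: np.ndarray  # on the standardised scale
    intercept: float
    center: np.ndarray
    scale: np.ndarray
    separation_flag: bool = False

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        x = table[list(self.spec.predictors)].to_numpy(dtype=float)
        z = (x - self.center) / self.scale
        eta = z @ self.coef + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))

    def predict_class(self, table: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(table) >= threshold).astype(int)


def _design(table: pd.DataFrame, spec: ModelSpec):
    missing = [c for c in spec.predictors if c not in table.columns]
    if missing:
        raise KeyError(
            f"missing predictors {missing}: run the density FPCA stage first"
            if any(c.startswith("fpc") for c in missing)
            else f"missing predictors {missing}"
        )
    x = table[list(spec.predictors)].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("missing values in predictors")
    return x


def fit_logistic(
    feature_table: pd.DataFrame,
    model_spec: ModelSpec | str,
    max_iter: int = 500,
) -> FittedLogistic:
    """Maximum-likelihood logistic fit with internal standardisation.

    Perfect separation is flagged with a warning (finite-iteration stop), not
    silent divergence.
    """
    spec = MODEL_SPECS[model_spec] if isinstance(model_spec, str) else model_spec
    x = _design(feature_table, spec)
    y = _binary_labels(feature_table["class_label"])
    center = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale == 0] = 1.0
    z = (x - center) / scale
    clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lbfgs convergence noise handled below
        clf.fit(z, y)
    coef = clf.coef_.ravel().copy()
    intercept = float(clf.intercept_[0])
    eta = z @ coef + intercept
    prob = 1.0 / (1.0 + np.exp(-eta))
    # standardised |coef| ~ 8 corresponds to an odds ratio of ~3000 per SD;
    # together with error-free in-sample prediction this signals separation
    separated = bool(
        np.abs(coef).max() > 8.0 and np.all((prob > 0.5) == (y == 1))
    )
    if separated:
        warnings.warn(
            f"{spec.name}: perfect separation detected; coefficients are the "
            f"finite-iteration stop after {max_iter} iterations",
            PerfectSeparationWarning,
            stacklevel=2,
        )
    return FittedLogistic(spec, coef, intercept, center, scale, separated)


# ---------------------------------------------------------------------------
# repeated stratified k-fold cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CVResult:
    spec: ModelSpec
    n_splits: int
    n_repeats: int
    seed: int
    oof_probs: np.ndarray  # (n_repeats, n) out-of-fold probabilities
    auc_per_repeat: np.ndarray
    accuracy_per_repeat: np.ndarray
    sensitivity_per_repeat: np.ndarray
    specificity_per_repeat: np.ndarray

    def _summary(self, arr: np.ndarray) -> tuple[float, float, float]:
        return (
            float(arr.mean()),
            float(np.quantile(arr, 0.025)),
            float(np.quantile(arr, 0.975)),
        )

    @property
    def auc(self):
        return self._summary(self.auc_per_repeat)

    @property
    def accuracy(self):
        return self._summary(self.accuracy_per_repeat)

    @property
    def sensitivity(self):
        return self._summary(self.sensitivity_per_repeat)

    @property
    def specificity(self):
        return self._summary(self.specificity_per_repeat)


def repeated_kfold_cv(
    feature_table: pd.DataFrame,
    model_spec: ModelSpec | str,
    n_splits: int = 10,
    n_repeats: int = 100,
    seed: int = 0,
    threshold: float = 0.5,
) -> CVResult:
    """Repeated stratified k-fold CV of a logistic model.

    All preprocessing (standardisation) is learned inside training folds;
    AUC is computed on the pooled out-of-fold probabilities of each repeat
    and summarised by the mean with a 2.5/97.5-percentile interval across
    repeats.  Fold draws come from per-repeat RNG streams spawned from the
    master seed, so repeats are independent and reproducible.
    """
    spec = MODEL_SPECS[model_spec] if isinstance(model_spec, str) else model_spec
    x_check = _design(feature_table, spec)  # early validation
    y = _binary_labels(feature_table["class_label"])
    n = y.size
    if min(y.sum(), n - y.sum()) < n_splits:
        raise ValueError("each class must have at least n_splits members")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_repeats) % (2**31)
    oof = np.empty((n_repeats, n))
    auc_r = np.empty(n_repeats)
    acc_r = np.empty(n_repeats)
    sens_r = np.empty(n_repeats)
    spec_r = np.empty(n_repeats)
    for r in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=int(child_seeds[r]))
        probs = np.empty(n)
        for train, test in skf.split(x_check, y):
            fit = fit_logistic(feature_table.iloc[train], spec)
            probs[test] = fit.predict_proba(feature_table.iloc[test])
        oof[r] = probs
        auc_r[r] = auc_mann_whitney(probs, y)
        pred = (probs >= threshold).astype(int)
        acc_r[r] = float((pred == y).mean())
        sens_r[r] = float(pred[y == 1].mean())
        spec_r[r] = float(1.0 - pred[y == 0].mean())
    return CVResult(spec, n_splits, n_repeats, seed, oof, auc_r, acc_r, sens_r, spec_r)


# ---------------------------------------------------------------------------
# bootstrap optimism-corrected calibration
# ---------------------------------------------------------------------------


@dataclass
class CalibrationResult:
    spec: ModelSpec
    mean_absolute_calibration_error: float
    curve: pd.DataFrame  # columns: predicted, observed_corrected
    n_bootstrap: int


def _smooth_calibration(y: np.ndarray, p: np.ndarray, eval_at: np.ndarray) -> np.ndarray:
    fit = lowess(y, p, frac=2.0 / 3.0, it=0, xvals=eval_at)
    return np.clip(fit, 0.0, 1.0)


def calibration_error(
    feature_table: pd.DataFrame,
    model_spec: ModelSpec | str,
    n_bootstrap: int = 200,
    seed: int = 0,
    prob_transform=None,
) -> CalibrationResult:
    """Optimism-corrected smooth calibration curve and its mean absolute error.

    The apparent lowess calibration of the full-data model is corrected by
    the average bootstrap optimism (apparent-on-bootstrap minus
    test-on-original, evaluated on the original prediction grid); the error
    is the mean |corrected probability - predicted probability|.
    ``prob_transform`` optionally distorts every predicted probability before
    scoring (diagnostic hook for studying induced miscalibration).
    """
    if n_bootstrap < 20:
        raise ValueError("n_bootstrap < 20 gives an unstable optimism estimate")
    transform = prob_transform if prob_transform is not None else (lambda p: p)
    spec = MODEL_SPECS[model_spec] if isinstance(model_spec, str) else model_spec
    y = _binary_labels(feature_table["class_label"])
    fit = fit_logistic(feature_table, spec)
    p_orig = transform(fit.predict_proba(feature_table))
    grid = np.sort(p_orig)
    apparent = _smooth_calibration(y, p_orig, grid)
    rng = np.random.default_rng(seed)
    n = y.size
    optimism = np.zeros_like(grid)
    done = 0
    attempts = 0
    while done < n_bootstrap and attempts < 20 * n_bootstrap:
        attempts += 1
        take = rng.integers(0, n, size=n)
        yb = y[take]
        if yb.min() == yb.max():
            continue
        tb = feature_table.iloc[take]
        fit_b = fit_logistic(tb, spec)
        pb_on_b = transform(fit_b.predict_proba(tb))
        pb_on_orig = transform(fit_b.predict_proba(feature_table))
        app_b = _smooth_calibration(yb, pb_on_b, grid)
        test_b = _smooth_calibration(y, pb_on_orig, grid)
        optimism += app_b - test_b
        done += 1
    if done == 0:
        raise ValueError("bootstrap failed: could not draw two-class resamples")
    corrected = np.clip(apparent - optimism / done, 0.0, 1.0)
    mace = float(np.mean(np.abs(corrected - grid)))
    curve = pd.DataFrame({"predicted": grid, "observed_corrected": corrected})
    return CalibrationResult(spec, mace, curve, done)


# ---------------------------------------------------------------------------
# full evaluation report
# ---------------------------------------------------------------------------


@dataclass
class ModelEvaluation:
    table3: pd.DataFrame
    correlations: CorrelationScreen
    table4: pd.DataFrame
    cv_results: dict[str, CVResult]
    calibration: dict[str, CalibrationResult]


def evaluate_models(
    feature_table: pd.DataFrame,
    seed: int = 0,
    n_splits: int = 10,
    n_repeats: int = 100,
    n_bootstrap_auc: int = 2000,
    calibration_bootstrap: int = 200,
    corr_threshold: float = 0.9,
    model_specs: dict[str, ModelSpec] | None = None,
) -> ModelEvaluation:
    """Univariate screening table, correlogram, and the three CV model rows.

    Deterministic given the seed.  Requires the feature table to carry the
    FPC score columns (fpc1, fpc2).
    """
    specs = model_specs or MODEL_SPECS
    missing_fpc = [c for c in ("fpc1", "fpc2") if c not in feature_table.columns]
    if missing_fpc:
        raise KeyError(
            f"feature table lacks {missing_fpc}: run the density FPCA stage first"
        )
    ss = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    rows = []
    auc_map = {}
    for i, feat in enumerate(TABLE3_PREDICTORS):
        roc = univariate_auc(
            feature_table[feat],
            feature_table["class_label"],
            n_bootstrap=n_bootstrap_auc,
            seed=int(ss[0]) + i,
        )
        auc_map[feat] = roc.auc
        rows.append(
            {
                "predictor": feat,
                "auc": roc.auc,
                "ci_low": roc.ci_low,
                "ci_high": roc.ci_high,
                "p_value": roc.p_value,
                "sensitivity": roc.sensitivity,
                "specificity": roc.specificity,
                "best_threshold": roc.best_threshold,
                "direction": roc.direction,
            }
        )
    table3 = (
        pd.DataFrame(rows)
        .sort_values(["auc", "predictor"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    screen = correlation_screen(
        feature_table, TABLE3_PREDICTORS, threshold=corr_threshold, auc_by_feature=auc_map
    )
    cv_results = {}
    calib = {}
    rows4 = []
    for name, spec in specs.items():
        cv = repeated_kfold_cv(
            feature_table, spec, n_splits=n_splits, n_repeats=n_repeats, seed=int(ss[1])
        )
        cv_results[name] = cv
        cal = calibration_error(
            feature_table, spec, n_bootstrap=calibration_bootstrap, seed=int(ss[2])
        )
        calib[name] = cal
        auc_m, auc_lo, auc_hi = cv.auc
        acc_m, acc_lo, acc_hi = cv.accuracy
        rows4.append(
            {
                "model": name,
                "predictors": "+".join(spec.predictors),
                "auc": auc_m,
                "auc_ci_low": auc_lo,
                "auc_ci_high": auc_hi,
                "accuracy": acc_m,
                "accuracy_ci_low": acc_lo,
                "accuracy_ci_high": acc_hi,
                "sensitivity": cv.sensitivity[0],
                "specificity": cv.specificity[0],
                "calibration_error": cal.mean_absolute_calibration_error,
            }
        )
    table4 = pd.DataFrame(rows4)
    return ModelEvaluation(table3, screen, table4, cv_results, calib)
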