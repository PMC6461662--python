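"""Synthetic subsolid-nodule cohort generation.

The study cohort this package analyses (56 pre-/minimally-invasive "T1"
nodules vs 53 invasive "T2" nodules, with per-nodule CT-attenuation
histograms and geometric measurements) is not publicly deposited, so this
module generates seeded surrogate cohorts whose per-class feature
distributions are calibrated, in closed form, to the published per-class
medians and inter-quartile ranges:

* nodule volume and mean diameter: log-normal, solved from (median, IQR);
* max/min diameter ratio: 1 + log-normal;
* consolidation ratio: logit-normal on (0, 1);
* per-nodule histogram mean HU: normal (median = location, IQR = 1.349 sigma).

Each nodule's attenuation histogram is drawn from a two-component Gaussian
mixture truncated to the scanner-relevant window [-1000, 500] HU: a broad
low-attenuation ground-glass component and a narrower high-attenuation solid
component whose mixture weight grows with the consolidation ratio
(w = w_max * cr^3, a volume-fraction proxy).  The ground-glass location is
solved per nodule so the truncated-mixture mean equals the drawn target mean,
which makes the class medians of the realised histogram means match the
calibration constants by construction.

A Gaussian copula on the six base variables (volume, mean diameter, diameter
ratio, consolidation ratio, mean HU, ground-glass SD) induces realistic
rank correlation (HU features strongly inter-correlated, size features
inter-correlated) while leaving every calibrated marginal untouched.

A reader-perturbation model (multiplicative log-normal jitter on geometry,
additive HU jitter on histogram bin locations) emulates the second reader's
independent segmentation for the downstream agreement analysis.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit, ndtr

__all__ = [
    "SUPPORT_HU",
    "AttenuationHistogram",
    "NoduleRecord",
    "ClassModel",
    "HistogramModel",
    "ReaderNoise",
    "GeneratorConfig",
    "CohortDataset",
    "ConfigurationError",
    "generate_cohort",
    "sample_histogram",
    "perturb_reader",
    "write_cohort",
    "read_cohort",
]

SUPPORT_HU = (-1000.0, 500.0)

#: standard normal quantile at p = 0.75, used by the closed-form calibrators
_Z75 = 0.6744897501960817

_T1_SUBTYPE_COUNTS = {"AAH": 3, "AIS": 24, "MIA": 29}

#: order of the base variables in the latent correlation matrix
BASE_VARIABLES = (
    "volume",
    "mean_diameter",
    "diameter_ratio",
    "consolidation_ratio",
    "mean_hu",
    "gg_sd",
)


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AttenuationHistogram:
    """Binned HU voxel counts for one nodule."""

    bin_centers: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        centers = np.asarray(self.bin_centers, dtype=float)
        counts = np.asarray(self.counts)
        if centers.ndim != 1 or counts.shape != centers.shape:
            raise ValueError("bin_centers and counts must be 1-D and aligned")
        if centers.size < 1:
            raise ValueError("empty histogram")
        if centers.size > 1:
            spacing = np.diff(centers)
            if np.any(spacing <= 0):
                raise ValueError("bin_centers must be strictly increasing")
            if not np.allclose(spacing, spacing[0], rtol=1e-9, atol=1e-9):
                raise ValueError("bin_centers must be uniformly spaced")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=1e-9):
                raise ValueError("counts must be integers")
            counts = rounded
        counts = counts.astype(np.int64)
        if counts.sum() <= 0:
            raise ValueError("histogram must contain at least one voxel")
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "counts", counts)

    @property
    def total_voxels(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_width(self) -> float:
        if self.bin_centers.size == 1:
            return 1.0
        return float(self.bin_centers[1] - self.bin_centers[0])


@dataclass(frozen=True)
class NoduleRecord:
    """One nodule: pathology label, geometry, and its attenuation histogram."""

    nodule_id: str
    class_label: str
    pathology_subtype: str
    volume_mm3: float
    min_diameter_mm: float
    max_diameter_mm: float
    mean_diameter_mm: float
    max_consolidation_mm: float
    histogram: AttenuationHistogram

    def __post_init__(self) -> None:
        if self.class_label not in ("T1", "T2"):
            raise ValueError(f"unknown class label {self.class_label!r}")
        t1_subtypes = set(_T1_SUBTYPE_COUNTS)
        if self.class_label == "T1" and self.pathology_subtype not in t1_subtypes:
            raise ValueError("T1 subtype must be AAH, AIS or MIA")
        if self.class_label == "T2" and self.pathology_subtype != "IPA":
            raise ValueError("T2 subtype must be IPA")
        if self.volume_mm3 <= 0:
            raise ValueError("volume must be positive")
        if not (0 < self.min_diameter_mm <= self.mean_diameter_mm <= self.max_diameter_mm):
            raise ValueError("diameters must satisfy 0 < min <= mean <= max")
        if not (0 <= self.max_consolidation_mm <= self.max_diameter_mm):
            raise ValueError("max consolidation must lie in [0, max diameter]")


@dataclass(frozen=True)
class ClassModel:
    """Per-class calibration constants (medians and IQRs of the base features).

    Units: volume mm^3, diameters mm, HU for attenuation quantities.  The
    ground-glass component SD is a log-normal nuisance parameter controlling
    per-nodule histogram spread (hence the per-nodule IQR/SD features).
    """

    volume_median: float
    volume_iqr: float
    diameter_median: float
    diameter_iqr: float
    diameter_ratio_median: float
    diameter_ratio_iqr: float
    consolidation_median: float
    consolidation_iqr: float
    mean_hu_median: float
    mean_hu_iqr: float
    gg_sd_median: float
    gg_sd_log_sd: float = 0.2

    def __post_init__(self) -> None:
        for name in (
            "volume_median",
            "volume_iqr",
            "diameter_median",
            "diameter_iqr",
            "diameter_ratio_iqr",
            "consolidation_iqr",
            "mean_hu_iqr",
            "gg_sd_median",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.diameter_ratio_median <= 1:
            raise ConfigurationError("diameter ratio median must exceed 1")
        if not 0 < self.consolidation_median < 1:
            raise ConfigurationError("consolidation median must lie in (0, 1)")
        if self.gg_sd_log_sd < 0:
            raise ConfigurationError("gg_sd_log_sd must be non-negative")


def t1_class_model() -> ClassModel:
    """Calibration constants of the pre-/minimally-invasive (T1) class."""
    return ClassModel(
        volume_median=1129.0,
        volume_iqr=2218.0,
        diameter_median=14.0,
        diameter_iqr=6.0,
        diameter_ratio_median=1.37,
        diameter_ratio_iqr=0.40,
        consolidation_median=0.29,
        consolidation_iqr=0.47,
        mean_hu_median=-639.0,
        mean_hu_iqr=169.0,
        gg_sd_median=150.0,
    )


def t2_class_model() -> ClassModel:
    """Calibration constants of the invasive adenocarcinoma (T2) class."""
    return ClassModel(
        volume_median=3459.0,
        volume_iqr=5754.0,
        diameter_median=20.0,
        diameter_iqr=14.0,
        diameter_ratio_median=1.67,
        diameter_ratio_iqr=0.57,
        consolidation_median=0.76,
        consolidation_iqr=0.43,
        mean_hu_median=-442.0,
        mean_hu_iqr=225.5,
        gg_sd_median=190.0,
    )


@dataclass(frozen=True)
class HistogramModel:
    """Shared parameters of the truncated two-component attenuation mixture."""

    solid_mean_hu: float = 50.0
    solid_sd_hu: float = 120.0
    solid_fraction_max: float = 0.4
    bin_width: float = 10.0
    support: tuple[float, float] = SUPPORT_HU

    def __post_init__(self) -> None:
        if self.solid_sd_hu <= 0:
            raise ConfigurationError("solid_sd_hu must be positive")
        if not 0 <= self.solid_fraction_max <= 1:
            raise ConfigurationError("solid_fraction_max must lie in [0, 1]")
        if self.bin_width <= 0:
            raise ConfigurationError("bin_width must be positive")
        lo, hi = self.support
        if hi <= lo:
            raise ConfigurationError("support must be a non-empty interval")

    @property
    def bin_centers(self) -> np.ndarray:
        lo, hi = self.support
        n = int(round((hi - lo) / self.bin_width)) + 1
        return lo + self.bin_width * np.arange(n)


@dataclass(frozen=True)
class ReaderNoise:
    """Perturbation magnitudes of the second-reader segmentation model.

    ``volume_sd_log``/``diameter_sd_log``/``consolidation_sd_log`` are SDs of
    multiplicative log-normal jitter; ``hu_sd`` (HU) is the SD of the additive
    Gaussian jitter applied to histogram bin locations before re-binning
    (which relocates, never deletes, voxels).  Defaults are calibrated once so
    the downstream model-1 predicted-class agreement matches the reported
    inter-reader kappa of 0.95.
    """

    volume_sd_log: float = 0.10
    diameter_sd_log: float = 0.05
    consolidation_sd_log: float = 0.10
    hu_sd: float = 20.0

    def __post_init__(self) -> None:
        for name in ("volume_sd_log", "diameter_sd_log", "consolidation_sd_log", "hu_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def scaled(self, factor: float) -> "ReaderNoise":
        if factor < 0:
            raise ValueError("noise scale factor must be non-negative")
        return ReaderNoise(
            volume_sd_log=self.volume_sd_log * factor,
            diameter_sd_log=self.diameter_sd_log * factor,
            consolidation_sd_log=self.consolidation_sd_log * factor,
            hu_sd=self.hu_sd * factor,
        )


def default_latent_correlation() -> np.ndarray:
    """Latent Gaussian copula correlation among the base variables.

    Qualitative structure: volume and diameter strongly related; the HU
    quantities (mean HU, consolidation ratio, ground-glass SD) moderately to
    strongly inter-related; the irregularity ratio nearly independent.
    """
    r = np.array(
        [
            # vol   diam  ratio  cons  mhu   ggsd
            [1.00, 0.85, 0.10, 0.20, 0.25, 0.20],  # volume
            [0.85, 1.00, 0.10, 0.20, 0.25, 0.20],  # mean diameter
            [0.10, 0.10, 1.00, 0.10, 0.10, 0.10],  # diameter ratio
            [0.20, 0.20, 0.10, 1.00, 0.60, 0.30],  # consolidation ratio
            [0.25, 0.25, 0.10, 0.60, 1.00, 0.45],  # mean HU
            [0.20, 0.20, 0.10, 0.30, 0.45, 1.00],  # ground-glass SD
        ]
    )
    return r


@dataclass(frozen=True)
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator."""

    n_t1: int = 56
    n_t2: int = 53
    t1: ClassModel = field(default_factory=t1_class_model)
    t2: ClassModel = field(default_factory=t2_class_model)
    histogram: HistogramModel = field(default_factory=HistogramModel)
    reader_noise: ReaderNoise = field(default_factory=ReaderNoise)
    latent_corr: np.ndarray = field(default_factory=default_latent_correlation)
    voxel_volume_mm3: float = 0.7 * 0.7 * 2.5
    max_voxels: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_t1 < 2 or self.n_t2 < 2:
            raise ConfigurationError("need at least 2 nodules per class")
        corr = np.asarray(self.latent_corr, dtype=float)
        k = len(BASE_VARIABLES)
        if corr.shape != (k, k):
            raise ConfigurationError(f"latent_corr must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigurationError("latent_corr must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigurationError("latent_corr must have unit diagonal")
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ConfigurationError("latent_corr must be positive semi-definite")
        if self.voxel_volume_mm3 <= 0:
            raise ConfigurationError("voxel volume must be positive")
        object.__setattr__(self, "latent_corr", corr)

    def to_json(self) -> str:
        def default(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj).__name__)

        return json.dumps(dataclasses.asdict(self), default=default, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        raw = json.loads(text)
        raw["t1"] = ClassModel(**raw["t1"])
        raw["t2"] = ClassModel(**raw["t2"])
        hist = raw["histogram"]
        hist["support"] = tuple(hist["support"])
        raw["histogram"] = HistogramModel(**hist)
        raw["reader_noise"] = ReaderNoise(**raw["reader_noise"])
        raw["latent_corr"] = np.asarray(raw["latent_corr"], dtype=float)
        return cls(**raw)


@dataclass
class CohortDataset:
    """A generated cohort: an ordered list of nodules plus its configuration."""

    records: list[NoduleRecord]
    config: GeneratorConfig

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def labels(self) -> np.ndarray:
        return np.array([r.class_label for r in self.records])


# ---------------------------------------------------------------------------
# closed-form marginal calibrators
# ---------------------------------------------------------------------------


def lognormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and inter-quartile range.

    IQR = median * 2 sinh(z75 * sigma) gives sigma in closed form.
    """
    if median <= 0 or iqr <= 0:
        raise ConfigurationError("median and IQR must be positive")
    sigma = float(np.arcsinh(iqr / (2.0 * median)) / _Z75)
    return float(np.log(median)), sigma


def logitnormal_from_median_iqr(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a logit-normal on (0,1) with given median and IQR."""
    if not 0 < median < 1:
        raise ConfigurationError("median must lie in (0, 1)")
    mu = float(logit(median))

    def iqr_of(sigma: float) -> float:
        return float(expit(mu + _Z75 * sigma) - expit(mu - _Z75 * sigma))

    if iqr <= 0 or iqr >= iqr_of(50.0):
        raise ConfigurationError("IQR unattainable for a logit-normal with this median")
    sigma = brentq(lambda s: iqr_of(s) - iqr, 1e-9, 50.0, xtol=1e-12)
    return mu, float(sigma)


def _truncnorm_mean(mu, sigma, lo, hi):
    """Mean of N(mu, sigma^2) truncated to [lo, hi]; vectorised in mu."""
    mu = np.asarray(mu, dtype=float)
    a = (lo - mu) / sigma
    b = (hi - mu) / sigma
    z = ndtr(b) - ndtr(a)
    phi = lambda x: np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = mu + sigma * (phi(a) - phi(b)) / z
    # degenerate truncation windows: fall back to the nearest bound
    out = np.where(np.isfinite(out), out, np.clip(mu, lo, hi))
    return out


def _solve_gg_location(target, sigma, lo, hi):
    """Location mu with truncated-normal mean == target, by vectorised bisection.

    The reachable mean range is limited by the truncation window; targets
    outside it are clamped to the nearest attainable value.
    """
    target = np.asarray(target, dtype=float)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=float), target.shape).copy()
    g_lo = np.full_like(target, lo - 3.5 * sigma.max())
    g_hi = np.full_like(target, hi - 1.0)
    m_lo = _truncnorm_mean(g_lo, sigma, lo, hi)
    m_hi = _truncnorm_mean(g_hi, sigma, lo, hi)
    t = np.clip(target, m_lo + 1e-9, m_hi - 1e-9)
    for _ in range(60):
        g_mid = 0.5 * (g_lo + g_hi)
        m_mid = _truncnorm_mean(g_mid, sigma, lo, hi)
        below = m_mid < t
        g_lo = np.where(below, g_mid, g_lo)
        g_hi = np.where(below, g_hi, g_mid)
    return 0.5 * (g_lo + g_hi)


def _mixture_bin_probs(
    gg_mean: float,
    gg_sd: float,
    solid_weight: float,
    model: HistogramModel,
) -> np.ndarray:
    """Per-bin probabilities of the support-truncated two-component mixture."""
    lo, hi = model.support
    centers = model.bin_centers
    edges = np.concatenate(
        [[lo], 0.5 * (centers[1:] + centers[:-1]), [hi]]
    )

    def comp_probs(mu, sd):
        cdf = ndtr((edges - mu) / sd)
        mass = cdf[-1] - cdf[0]
        if mass <= 0:
            raise ValueError("mixture component has no mass inside the support")
        return np.diff(cdf) / mass

    w = float(solid_weight)
    probs = (1.0 - w) * comp_probs(gg_mean, gg_sd)
    if w > 0:
        probs = probs + w * comp_probs(model.solid_mean_hu, model.solid_sd_hu)
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def sample_histogram(
    class_label: str,
    params: dict,
    rng: np.random.Generator,
    model: HistogramModel | None = None,
) -> AttenuationHistogram:
    """Draw one attenuation histogram from a truncated Gaussian mixture.

    ``params`` holds ``gg_mean``, ``gg_sd``, ``solid_weight`` and
    ``total_voxels``.  Raises if more than half of the untruncated mixture
    mass falls outside the attenuation support.
    """
    if class_label not in ("T1", "T2"):
        raise ValueError("class_label must be 'T1' or 'T2'")
    model = model or HistogramModel()
    lo, hi = model.support
    gg_mean = float(params["gg_mean"])
    gg_sd = float(params["gg_sd"])
    w = float(params["solid_weight"])
    total = int(params["total_voxels"])
    if not 0 <= w <= 1:
        raise ValueError("solid_weight must lie in [0, 1]")
    if gg_sd <= 0 or total <= 0:
        raise ValueError("gg_sd and total_voxels must be positive")

    def inside_mass(mu, sd):
        return float(ndtr((hi - mu) / sd) - ndtr((lo - mu) / sd))

    mass_inside = (1 - w) * inside_mass(gg_mean, gg_sd) + w * inside_mass(
        model.solid_mean_hu, model.solid_sd_hu
    )
    if mass_inside < 0.5:
        raise ValueError(
            "more than 50% of the mixture mass lies outside the attenuation support"
        )
    probs = _mixture_bin_probs(gg_mean, gg_sd, w, model)
    counts = rng.multinomial(total, probs)
    return AttenuationHistogram(model.bin_centers, counts)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _generate_class(
    class_label: str,
    n: int,
    cm: ClassModel,
    config: GeneratorConfig,
    rng: np.random.Generator,
) -> list[NoduleRecord]:
    hist_model = config.histogram
    lo, hi = hist_model.support

    chol = np.linalg.cholesky(
        config.latent_corr + 1e-12 * np.eye(len(BASE_VARIABLES))
    )
    z = rng.standard_normal((n, len(BASE_VARIABLES))) @ chol.T

    mu_v, s_v = lognormal_from_median_iqr(cm.volume_median, cm.volume_iqr)
    mu_d, s_d = lognormal_from_median_iqr(cm.diameter_median, cm.diameter_iqr)
    mu_r, s_r = lognormal_from_median_iqr(
        cm.diameter_ratio_median - 1.0, cm.diameter_ratio_iqr
    )
    mu_c, s_c = logitnormal_from_median_iqr(cm.consolidation_median, cm.consolidation_iqr)

    volume = np.exp(mu_v + s_v * z[:, 0])
    mean_diam = np.exp(mu_d + s_d * z[:, 1])
    ratio = 1.0 + np.exp(mu_r + s_r * z[:, 2])
    cons_ratio = expit(mu_c + s_c * z[:, 3])
    mean_hu = cm.mean_hu_median + (cm.mean_hu_iqr / (2 * _Z75)) * z[:, 4]
    gg_sd = np.exp(np.log(cm.gg_sd_median) + cm.gg_sd_log_sd * z[:, 5])

    min_diam = mean_diam / np.sqrt(ratio)
    max_diam = mean_diam * np.sqrt(ratio)
    max_cons = cons_ratio * max_diam

    solid_w = hist_model.solid_fraction_max * cons_ratio**3
    # keep per-nodule mean targets inside the window reachable by the mixture
    solid_mean_trunc = _truncnorm_mean(
        np.array(hist_model.solid_mean_hu), hist_model.solid_sd_hu, lo, hi
    )
    target_gg_mean = (np.clip(mean_hu, lo + 110.0, hi - 60.0) - solid_w * solid_mean_trunc) / (
        1.0 - solid_w
    )
    gg_mean = _solve_gg_location(target_gg_mean, gg_sd, lo, hi)

    total_voxels = np.maximum(
        np.rint(volume / config.voxel_volume_mm3).astype(int), 50
    )
    total_voxels = np.minimum(total_voxels, config.max_voxels)

    subtypes: list[str]
    if class_label == "T1":
        pattern = [s for s, c in _T1_SUBTYPE_COUNTS.items() for _ in range(c)]
        reps = int(np.ceil(n / len(pattern)))
        subtypes = sorted(
            (pattern * reps)[:n], key=lambda s: list(_T1_SUBTYPE_COUNTS).index(s)
        )
    else:
        subtypes = ["IPA"] * n

    records = []
    for i in range(n):
        probs = _mixture_bin_probs(
            float(gg_mean[i]), float(gg_sd[i]), float(solid_w[i]), hist_model
        )
        counts = rng.multinomial(int(total_voxels[i]), probs)
        hist = AttenuationHistogram(hist_model.bin_centers, counts)
        records.append(
            NoduleRecord(
                nodule_id=f"{class_label}-{i + 1:03d}",
                class_label=class_label,
                pathology_subtype=subtypes[i],
                volume_mm3=float(volume[i]),
                min_diameter_mm=float(min_diam[i]),
                max_diameter_mm=float(max_diam[i]),
                mean_diameter_mm=float(mean_diam[i]),
                max_consolidation_mm=float(max_cons[i]),
                histogram=hist,
            )
        )
    return records


def generate_cohort(
    config: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
) -> CohortDataset:
    """Generate one synthetic cohort of ``n_t1 + n_t2`` nodules.

    Deterministic given ``config.seed`` (or an explicitly supplied ``rng``).
    """
    config = config or GeneratorConfig()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    records = _generate_class("T1", config.n_t1, config.t1, config, rng)
    records += _generate_class("T2", config.n_t2, config.t2, config, rng)
    return CohortDataset(records=records, config=config)


# ---------------------------------------------------------------------------
# reader perturbation
# ---------------------------------------------------------------------------


def _jitter_histogram(
    hist: AttenuationHistogram, hu_sd: float, rng: np.random.Generator
) -> AttenuationHistogram:
    """Relocate each bin's voxels by an additive HU offset, then re-bin.

    Total voxel count is conserved by construction.
    """
    if hu_sd == 0:
        return hist
    centers = hist.bin_centers
    width = hist.bin_width
    offsets = rng.normal(0.0, hu_sd, size=centers.size)
    new_pos = centers + offsets
    idx = np.clip(np.rint((new_pos - centers[0]) / width).astype(int), 0, centers.size - 1)
    counts = np.zeros_like(hist.counts)
    np.add.at(counts, idx, hist.counts)
    return AttenuationHistogram(centers, counts)


def perturb_reader(
    cohort: CohortDataset,
    reader_noise: ReaderNoise | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> CohortDataset:
    """Produce a second-reader variant of a cohort.

    Nodule identities and pathology labels are preserved; volumes, diameters
    and histograms are jittered.  Zero noise returns an identical copy.
    """
    noise = reader_noise if reader_noise is not None else cohort.config.reader_noise
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(0 if seed is None else seed))
    out = []
    for rec in cohort.records:
        vol = rec.volume_mm3 * float(np.exp(noise.volume_sd_log * rng.standard_normal()))
        diams = np.array([rec.min_diameter_mm, rec.mean_diameter_mm, rec.max_diameter_mm])
        diams = np.sort(diams * np.exp(noise.diameter_sd_log * rng.standard_normal(3)))
        cons = rec.max_consolidation_mm * float(
            np.exp(noise.consolidation_sd_log * rng.standard_normal())
        )
        cons = min(cons, float(diams[2]))
        hist = _jitter_histogram(rec.histogram, noise.hu_sd, rng)
        out.append(
            dataclasses.replace(
                rec,
                volume_mm3=vol,
                min_diameter_mm=float(diams[0]),
                mean_diameter_mm=float(diams[1]),
                max_diameter_mm=float(diams[2]),
                max_consolidation_mm=cons,
                histogram=hist,
            )
        )
    return CohortDataset(records=out, config=cohort.config)


# ---------------------------------------------------------------------------
# cohort export / import (plain-text CSV + JSON)
# ---------------------------------------------------------------------------

_COHORT_COLUMNS = [
    "nodule_id",
    "class_label",
    "pathology_subtype",
    "volume_mm3",
    "min_diameter_mm",
    "max_diameter_mm",
    "mean_diameter_mm",
    "max_consolidation_mm",
]


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write one cohort CSV, one histogram CSV per nodule, and the config JSON.

    Floats are written with ``repr`` (shortest round-trip), so a read-back is
    bit-exact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort_path = out_dir / "cohort.csv"
    with open(cohort_path, "w") as fh:
        fh.write(",".join(_COHORT_COLUMNS) + "\n")
        for rec in cohort.records:
            row = [
                rec.nodule_id,
                rec.class_label,
                rec.pathology_subtype,
                repr(rec.volume_mm3),
                repr(rec.min_diameter_mm),
                repr(rec.max_diameter_mm),
                repr(rec.mean_diameter_mm),
                repr(rec.max_consolidation_mm),
            ]
            fh.write(",".join(row) + "\n")
    for rec in cohort.records:
        with open(out_dir / f"{rec.nodule_id}_hist.csv", "w") as fh:
            fh.write("hu_bin_center,count\n")
            for c, k in zip(rec.histogram.bin_centers, rec.histogram.counts):
                fh.write(f"{repr(float(c))},{int(k)}\n")
    config_path = out_dir / "config.json"
    config_path.write_text(cohort.config.to_json())
    return {"cohort": cohort_path, "config": config_path, "dir": out_dir}


def read_cohort(in_dir: str | Path) -> CohortDataset:
    """Read a cohort previously written by :func:`write_cohort`."""
    in_dir = Path(in_dir)
    config = GeneratorConfig.from_json((in_dir / "config.json").read_text())
    records = []
    with open(in_dir / "cohort.csv") as fh:
        header = fh.readline().strip().split(",")
        if header != _COHORT_COLUMNS:
            raise ValueError("unexpected cohort.csv header")
        for line in fh:
            parts = line.strip().split(",")
            nodule_id = parts[0]
            hist_rows = (in_dir / f"{nodule_id}_hist.csv").read_text().splitlines()[1:]
            centers, counts = zip(
                *((float(r.split(",")[0]), int(r.split(",")[1])) for r in hist_rows)
            )
            records.append(
                NoduleRecord(
                    nodule_id=nodule_id,
                    class_label=parts[1],
                    pathology_subtype=parts[2],
                    volume_mm3=float(parts[3]),
                    min_diameter_mm=float(parts[4]),
                    max_diameter_mm=float(parts[5]),
                    mean_diameter_mm=float(parts[6]),
                    max_consolidation_mm=float(parts[7]),
                    histogram=AttenuationHistogram(np.array(centers), np.array(counts)),
                )
            )
    return CohortDataset(records=records, config=config)
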