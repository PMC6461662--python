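"""End-to-end orchestration: simulate -> features -> FPCA -> evaluate -> agree.

A single seeded run generates the synthetic cohort and its second-reader
variant, computes the a-priori and FPC features, evaluates the three
logistic models by repeated cross-validation, measures inter-reader
agreement, and writes every report table (and the data behind the
mode-of-variation and score-scatter figures) as plain-text artifacts.
Identical seed and config give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement as agr
from . import cohort as coh
from . import features as feat
from . import fpca as fp
from . import modeling as mdl

__all__ = ["FPCAConfig", "ModelingConfig", "RunConfig", "RunReport", "run_pipeline",
           "compute_fpc_features", "PipelineError"]

_RNG_STREAMS = ("cohort", "reader", "cv", "bootstrap")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass(frozen=True)
class FPCAConfig:
    grid_size: int = 151
    pgrid_size: int = 101
    floor: float = 1e-5
    bandwidth: float | str = "auto"
    var_threshold: float = 0.85
    mode_levels: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)


@dataclass(frozen=True)
class ModelingConfig:
    n_splits: int = 10
    n_repeats: int = 100
    n_bootstrap: int = 2000
    calibration_bootstrap: int = 200
    corr_threshold: float = 0.9
    fpca_within_folds: bool = False


@dataclass(frozen=True)
class RunConfig:
    generator: coh.GeneratorConfig = field(default_factory=coh.GeneratorConfig)
    fpca: FPCAConfig = field(default_factory=FPCAConfig)
    modeling: ModelingConfig = field(default_factory=ModelingConfig)
    seed: int = 0

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        payload["generator"] = json.loads(self.generator.to_json())
        return json.dumps(payload, indent=2, sort_keys=True, default=str)


@dataclass
class RunReport:
    out_dir: Path
    paths: dict[str, Path]
    summary: dict


def _stream_seeds(master_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(master_seed).generate_state(len(_RNG_STREAMS))
    return {name: int(s % (2**31)) for name, s in zip(_RNG_STREAMS, state)}


def compute_fpc_features(
    cohort: coh.CohortDataset, config: FPCAConfig = FPCAConfig()
) -> tuple[pd.DataFrame, fp.FPCAModel, list[fp.LQDCurve]]:
    """Feature table with fpc1/fpc2 columns joined, plus the fitted FPCA model."""
    table = feat.assemble_feature_table(cohort)
    curves = []
    for rec in cohort.records:
        dens = fp.smooth_histogram_to_density(
            rec.histogram,
            bandwidth=config.bandwidth,
            floor=config.floor,
            grid_size=config.grid_size,
        )
        curves.append(fp.lqd_transform(dens, pgrid_size=config.pgrid_size))
    model = fp.fit_fpca(curves, var_threshold=config.var_threshold)
    table = table.copy()
    table["fpc1"] = model.scores[:, 0]
    table["fpc2"] = model.scores[:, 1] if model.n_components > 1 else 0.0
    return table, model, curves


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Run every stage and write all artifacts under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = _stream_seeds(config.seed)
    paths: dict[str, Path] = {}
    log_lines: list[str] = [f"seed={config.seed}", f"streams={seeds}"]

    def stage(name):
        log_lines.append(f"stage: {name}")

    try:
        stage("simulate")
        gen_cfg = dataclasses.replace(config.generator, seed=seeds["cohort"])
        cohort = coh.generate_cohort(gen_cfg)
        reader_rng = np.random.default_rng(np.random.SeedSequence(seeds["reader"]))
        cohort_b = coh.perturb_reader(cohort, rng=reader_rng)
        cohort_dir = out_dir / "cohort"
        paths.update({f"cohort_{k}": v for k, v in coh.write_cohort(cohort, cohort_dir).items()})
        log_lines.append(f"cohort: {len(cohort)} nodules")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"simulate stage failed: {exc}") from exc

    try:
        stage("features+fpca")
        fpca_cfg = config.fpca
        table, model, _curves = compute_fpc_features(cohort, fpca_cfg)
        table_b, _model_b, _ = compute_fpc_features(cohort_b, fpca_cfg)
        paths["feature_table"] = feat.write_feature_table(table, out_dir / "feature_table.csv")
        (out_dir / "fpca_model.json").write_text(model.to_json())
        paths["fpca_model"] = out_dir / "fpca_model.json"
        scatter = table[["nodule_id", "class_label", "fpc1", "fpc2"]]
        scatter.to_csv(out_dir / "fpc_scores.csv", index=False)
        paths["fpc_scores"] = out_dir / "fpc_scores.csv"
        for k in (1, 2):
            if k > model.n_components:
                break
            curves = fp.mode_of_variation(model, k, fpca_cfg.mode_levels,
                                          grid_size=fpca_cfg.grid_size)
            frame = pd.DataFrame({"hu": curves[0].grid})
            for lvl, c in zip(fpca_cfg.mode_levels, curves):
                frame[f"level_{lvl}"] = c.values
            frame.to_csv(out_dir / f"modes_fpc{k}.csv", index=False)
            paths[f"modes_fpc{k}"] = out_dir / f"modes_fpc{k}.csv"
        log_lines.append(
            f"fpca: {model.n_components} components, "
            f"var_explained={np.round(model.var_explained, 4).tolist()}"
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"features/fpca stage failed: {exc}") from exc

    try:
        stage("evaluate")
        m = config.modeling
        ev = mdl.evaluate_models(
            table,
            seed=seeds["cv"],
            n_splits=m.n_splits,
            n_repeats=m.n_repeats,
            n_bootstrap_auc=m.n_bootstrap,
            calibration_bootstrap=m.calibration_bootstrap,
            corr_threshold=m.corr_threshold,
        )
        ev.table3.to_csv(out_dir / "table3.csv", index=False)
        ev.table4.to_csv(out_dir / "table4.csv", index=False)
        ev.correlations.r.to_csv(out_dir / "correlogram.csv")
        calib = {
            name: {
                "mean_absolute_calibration_error": c.mean_absolute_calibration_error,
                "n_bootstrap": c.n_bootstrap,
            }
            for name, c in ev.calibration.items()
        }
        (out_dir / "calibration.json").write_text(json.dumps(calib, indent=2, sort_keys=True))
        paths.update(
            table3=out_dir / "table3.csv",
            table4=out_dir / "table4.csv",
            correlogram=out_dir / "correlogram.csv",
            calibration=out_dir / "calibration.json",
        )
        log_lines.append("evaluate: 3 model rows")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"evaluate stage failed: {exc}") from exc

    try:
        stage("agreement")
        res = agr.reader_agreement(
            table, table_b, "model1",
            n_bootstrap=config.modeling.n_bootstrap, seed=seeds["bootstrap"],
        )
        (out_dir / "agreement.json").write_text(json.dumps(res.to_dict(), indent=2, sort_keys=True))
        paths["agreement"] = out_dir / "agreement.json"
        log_lines.append(f"agreement: kappa={res.kappa.kappa:.4f} icc={res.icc.icc:.4f}")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"agreement stage failed: {exc}") from exc

    (out_dir / "config.json").write_text(config.to_json())
    paths["config"] = out_dir / "config.json"
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    paths["log"] = out_dir / "run.log"

    summary = {
        "n_nodules": len(cohort),
        "fpca_components": model.n_components,
        "var_explained": model.var_explained.tolist(),
        "table4": ev.table4.to_dict(orient="records"),
        "agreement": res.to_dict(),
    }
    return RunReport(out_dir=out_dir, paths=paths, summary=summary)
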