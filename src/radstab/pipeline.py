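"""End-to-end orchestration: simulate -> extract -> stability -> train -> evaluate.

One master seed drives every random stage (child seeds are spawned from
it), and every artifact records the hash of the configuration that
produced it, so a rerun with the same config file is bit-reproducible.
Feature tables are the only inter-stage contract: real co-registered
NIfTI inputs can replace the simulated ones at the extract stage and
everything downstream is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema
from .evaluation import evaluate_models, pool_longitudinal
from .extract import extract_all
from .image_io import write_labelmap, write_map_set
from .modeling import make_best_model, make_concordant_model
from .stability import stable_features
from .synthetic import PhantomConfig, simulate_phantom_pair, simulate_study
from .texture import DiscretizationPolicy

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("radstab")

STAGES = ("simulate", "extract", "stability", "train", "evaluate")


@dataclass
class RunConfig:
    """Single configuration for a full pipeline run."""

    master_seed: int = 0
    scenario: str = "stable_signal"     # or "unstable_signal"
    target: str = "IDH"                 # label written into reports
    n_cross: int = 312
    n_long: int = 38
    prevalence: float = 0.25
    n_features: int = 400
    icc_threshold: float = 0.5
    lambda_selection: str = "min"       # or "1se"
    cv_folds: int = 10
    n_bins: int = 32                    # texture discretization
    het_bins: int = 64                  # heterogeneity histograms
    simulate_phantom: bool = False      # also write a demo phantom + its features
    phantom_grid: int = 32
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        cfg = cls(**data)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    out_dir: Path
    config_hash: str
    reports: pd.DataFrame = field(default_factory=pd.DataFrame)
    artifacts: dict = field(default_factory=dict)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# radstab schema=1 config_hash={config_hash}\n")
        df.to_csv(fh)


def _read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunResult:
    """Run the configured stages; artifacts land in ``out_dir``.

    Stage toggles let a rerun skip e.g. simulation and pick saved
    feature tables up from disk; results are identical because the
    tables are the only contract between stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    result = RunResult(out_dir=out, config_hash=chash)

    seeds = np.random.SeedSequence(config.master_seed).spawn(4)
    seed_ints = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]

    try:
        t0 = time.time()
        logger.info("run start config_hash=%s stages=%s", chash, config.stages)
        (out / "config.yaml").write_text(
            yaml.safe_dump({**asdict(config), "config_hash": chash})
        )

        paths = {
            "cross": out / "features_cross.csv",
            "long_t1": out / "features_long_t1.csv",
            "long_t2": out / "features_long_t2.csv",
            "labels_cross": out / "labels_cross.csv",
            "labels_long": out / "labels_long.csv",
        }

        if "simulate" in config.stages:
            cross, longitudinal = simulate_study(
                config.scenario, seed_ints[0],
                n_cross=config.n_cross, n_long=config.n_long,
                prevalence=config.prevalence, n_features=config.n_features,
            )
            _write_table(cross.features_t1, paths["cross"], chash)
            _write_table(longitudinal.features_t1, paths["long_t1"], chash)
            _write_table(longitudinal.features_t2, paths["long_t2"], chash)
            _write_table(cross.labels.to_frame(), paths["labels_cross"], chash)
            _write_table(longitudinal.labels.to_frame(), paths["labels_long"], chash)
            _write_table(cross.truth, out / "truth.csv", chash)
            logger.info("simulate done (%.1fs)", time.time() - t0)

        if "extract" in config.stages and config.simulate_phantom:
            # demo volume-level path: phantom -> NIfTI -> 1720 features
            g = config.phantom_grid
            pcfg = PhantomConfig(grid_shape=(g, g, g), seed=seed_ints[1])
            map_set, rois = simulate_phantom_pair(pcfg)
            write_map_set(map_set, out / "phantom")
            write_labelmap(rois, out / "phantom" / "labelmap.nii.gz")
            vec, rep = extract_all(
                map_set, rois,
                policy=DiscretizationPolicy(n_bins=config.n_bins),
                het_bins=config.het_bins,
            )
            _write_table(vec.to_frame().T, out / "features_phantom.csv", chash)
            (out / "phantom_extraction_report.json").write_text(
                json.dumps(
                    {"n_features": rep.n_features, "n_missing": rep.n_missing,
                     "voxel_counts": rep.voxel_counts}, indent=1)
            )
            logger.info("extract done: %d features, %d missing",
                        rep.n_features, rep.n_missing)

        # downstream stages read the tables back from disk (the contract)
        cross_X = _read_table(paths["cross"])
        long_t1 = _read_table(paths["long_t1"])
        long_t2 = _read_table(paths["long_t2"])
        cross_y = _read_table(paths["labels_cross"])["genotype"]
        long_y = _read_table(paths["labels_long"])["genotype"]

        if "stability" in config.stages:
            report = stable_features(
                long_t1, long_t2,
                threshold=config.icc_threshold,
                genotype_context=config.target,
            )
            _write_table(report.to_frame(), out / "stability_report.csv", chash)
            (out / "stability_meta.json").write_text(json.dumps({
                "variant": report.variant, "n_subjects": report.n_subjects,
                "threshold": report.threshold, "context": report.genotype_context,
                "n_stable": len(report.stable_set), "config_hash": chash,
            }, indent=1))
            logger.info("stability done: %d/%d stable",
                        len(report.stable_set), long_t1.shape[1])

        models = []
        if "train" in config.stages:
            stab_df = _read_table(out / "stability_report.csv")
            from .stability import StabilityReport
            report = StabilityReport(
                icc_by_feature=stab_df["icc"],
                n_subjects=len(long_t1),
                threshold=config.icc_threshold,
                genotype_context=config.target,
            )
            best = make_best_model(
                cross_X, cross_y, target=config.target,
                cv_folds=config.cv_folds, seed=seed_ints[2],
                selection=config.lambda_selection,
            )
            concordant = make_concordant_model(
                cross_X, cross_y, report, target=config.target,
                cv_folds=config.cv_folds, seed=seed_ints[2],
                selection=config.lambda_selection,
            )
            (out / "models").mkdir(exist_ok=True)
            for m in (best, concordant):
                m.metadata["config_hash"] = chash
                m.to_json(out / "models" / f"{m.flavor}_{m.target}.json")
            models = [best, concordant]
            logger.info("train done: best=%d features, concordant=%d features",
                        len(best.selected), len(concordant.selected))

        if "evaluate" in config.stages:
            if not models:
                from .modeling import ModelSpec
                models = [
                    ModelSpec.from_json(p)
                    for p in sorted((out / "models").glob("*.json"))
                ]
            from .synthetic import SyntheticCohort
            pooled_X, pooled_y = pool_longitudinal(
                SyntheticCohort(features_t1=long_t1, features_t2=long_t2, labels=long_y)
            )
            cohorts = {
                "cross-sectional": (cross_X, cross_y),
                "longitudinal-pooled": (pooled_X, pooled_y),
            }
            reports = evaluate_models(models, cohorts)
            df = pd.DataFrame([r.as_dict() for r in reports])
            df["config_hash"] = chash
            _write_table(df.set_index(["flavor", "cohort"]), out / "performance.csv", chash)
            result.reports = df
            logger.info("evaluate done:\n%s",
                        df[["flavor", "cohort", "auc"]].to_string(index=False))

        logger.info("run complete (%.1fs)", time.time() - t0)
    except Exception as exc:  # halt with a stage-named error; keep partial artifacts
        logger.error("pipeline failed: %s", exc)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()

    result.artifacts = {p.name: p for p in out.iterdir()}
    return result
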