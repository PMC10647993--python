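"""Pipeline driver wiring the stages: simulate -> register -> prm -> stage ->
train -> evaluate, with a JSON-configurable entry point and a run manifest.

Each stage reads its inputs from disk (or from the preceding stage's output
directory), writes its artifacts under ``out_dir``, and records them with a
SHA-256 digest in ``run_manifest.json``, so a rerun with the same config and
seed is reproducible and partial reruns can resume from existing artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Any

import joblib
import numpy as np
import pandas as pd

from . import __version__, evaluation, io, models, prm, registration, staging, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

#: canonical stage order
STAGES = ("simulate_phantom", "register", "prm", "simulate_cohort", "stage", "train", "evaluate")


@dataclasses.dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` selects which stages run (executed in canonical order);
    per-stage settings blocks mirror the dataclasses of the corresponding
    modules.  Every stage derives its random seed from ``seed``.
    """

    out_dir: str = "prmlung_run"
    stages: tuple[str, ...] = STAGES
    seed: int = 0
    phantom: dict[str, Any] = dataclasses.field(default_factory=dict)
    cohort: dict[str, Any] = dataclasses.field(default_factory=dict)
    registration: dict[str, Any] = dataclasses.field(default_factory=dict)
    split_sizes: tuple[int, int] | None = None
    families: tuple[str, ...] = ("random_forest", "mlp")
    resume: bool = False
    cohort_csv: str | None = None  # use an existing cohort instead of simulating

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage names {unknown}; valid stages are {list(STAGES)}")
        self.stages = tuple(s for s in STAGES if s in self.stages)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "split_sizes" in raw and raw["split_sizes"] is not None:
            raw["split_sizes"] = tuple(raw["split_sizes"])
        if "families" in raw:
            raw["families"] = tuple(raw["families"])
        return cls(**raw)


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.path = out_dir / "run_manifest.json"
        self.data: dict[str, Any] = {
            "prmlung_version": __version__,
            "python": platform.python_version(),
            "seed": config.seed,
            "stages": list(config.stages),
            "config": {
                k: v for k, v in dataclasses.asdict(config).items() if k != "resume"
            },
            "artifacts": {},
        }

    def record(self, stage: str, files: dict[str, Path]) -> None:
        self.data["artifacts"].setdefault(stage, {})
        for name, p in files.items():
            self.data["artifacts"][stage][name] = {
                "path": str(p), "sha256": _digest(Path(p))
            }
        self.write()

    def write(self) -> None:
        with open(self.path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the selected stages; returns a summary with artifact paths.

    Raises a named error if a selected stage's inputs are missing; stages
    downstream of a failure are not run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out, config)
    summary: dict[str, Any] = {"out_dir": str(out)}

    phantom_dir = out / "phantom"
    registered_path = out / "registered_exp.nii.gz"
    field_path = out / "displacement.nii.gz"
    params_path = out / "params.csv"
    labelmap_path = out / "prm_labels.nii.gz"
    cohort_path = Path(config.cohort_csv) if config.cohort_csv else out / "cohort.csv"
    staged_path = out / "staged.csv"
    models_dir = out / "models"
    report_path = out / "report.json"

    for stage_name in config.stages:
        if stage_name == "simulate_phantom":
            if config.resume and (phantom_dir / "insp.nii.gz").exists():
                logger.info("resume: phantom exists, skipping")
            else:
                result = synthetic.generate_phantom_pair(
                    synthetic.PhantomConfig(seed=config.seed, **config.phantom)
                )
                files = io.write_phantom(phantom_dir, result)
                manifest.record(stage_name, files)
            summary["phantom"] = str(phantom_dir)

        elif stage_name == "register":
            if not (phantom_dir / "insp.nii.gz").exists():
                raise FileNotFoundError(
                    "register stage: no paired study found (run simulate_phantom "
                    f"or place volumes under {phantom_dir})"
                )
            if config.resume and registered_path.exists():
                logger.info("resume: registration exists, skipping")
            else:
                study = io.read_paired_study(
                    phantom_dir / "insp.nii.gz", phantom_dir / "exp.nii.gz",
                    phantom_dir / "lung_mask.nii.gz", phantom_dir / "lobe_mask.nii.gz",
                )
                settings = registration.RegistrationSettings(**config.registration)
                res = registration.register_exp_to_insp(study, settings)
                io.save_volume(registered_path, np.nan_to_num(res.registered_exp, nan=0.0),
                               study.spacing)
                io.save_field(field_path, res.field, study.spacing)
                manifest.record(stage_name, {"registered": registered_path, "field": field_path})
                summary["registration_converged"] = res.converged
            summary["registered"] = str(registered_path)

        elif stage_name == "prm":
            source = registered_path if registered_path.exists() else phantom_dir / "exp.nii.gz"
            if not (phantom_dir / "insp.nii.gz").exists():
                raise FileNotFoundError("prm stage: inspiratory volume missing")
            study = io.read_paired_study(
                phantom_dir / "insp.nii.gz", source,
                phantom_dir / "lung_mask.nii.gz", phantom_dir / "lobe_mask.nii.gz",
            )
            label_map = prm.compute_prm_map(study.insp, study.exp, study.lung_mask,
                                            spacing=study.spacing)
            vec = prm.aggregate_regions(label_map, study.lobe_mask)
            vec.to_frame().to_csv(params_path, index=False)
            io.save_volume(labelmap_path, label_map.labels.astype(np.int16), study.spacing)
            manifest.record(stage_name, {"params": params_path, "labelmap": labelmap_path})
            summary["params"] = str(params_path)

        elif stage_name == "simulate_cohort":
            if config.cohort_csv:
                logger.info("using existing cohort %s; simulate_cohort skipped", cohort_path)
            elif config.resume and cohort_path.exists():
                logger.info("resume: cohort exists, skipping")
            else:
                df = synthetic.generate_cohort(
                    synthetic.CohortConfig(seed=config.seed, **config.cohort)
                )
                io.write_cohort(df, cohort_path)
                manifest.record(stage_name, {"cohort": cohort_path})
            summary["cohort"] = str(cohort_path)

        elif stage_name == "stage":
            if not cohort_path.exists():
                raise FileNotFoundError(f"stage stage: cohort file {cohort_path} missing")
            df = io.read_cohort(cohort_path)
            staged = pd.concat(
                [df.reset_index(drop=True),
                 staging.classify_table(df["fev1_fvc"], df["fev1_pct"]).add_prefix("rule_")],
                axis=1,
            )
            staged.to_csv(staged_path, index=False)
            manifest.record(stage_name, {"staged": staged_path})
            summary["staged"] = str(staged_path)

        elif stage_name == "train":
            if not cohort_path.exists():
                raise FileNotFoundError(f"train stage: cohort file {cohort_path} missing")
            df = io.read_cohort(cohort_path)
            train_df, _ = models.split_train_validation(df, seed=config.seed,
                                                        sizes=config.split_sizes)
            models_dir.mkdir(exist_ok=True)
            files = {}
            for family in config.families:
                for target in models.TARGETS:
                    model = models.train_regressor(train_df, target, family=family,
                                                   seed=config.seed)
                    stem = f"{family}_{target}"
                    joblib.dump(model, models_dir / f"{stem}.joblib")
                    with open(models_dir / f"{stem}.json", "w") as fh:
                        json.dump({
                            "family": family, "target": target, "seed": config.seed,
                            "n_train": len(train_df),
                            "feature_order": models.FEATURE_COLUMNS,
                            "prmlung_version": __version__,
                        }, fh, indent=2)
                    files[stem] = models_dir / f"{stem}.joblib"
            manifest.record(stage_name, files)
            summary["models"] = str(models_dir)

        elif stage_name == "evaluate":
            if not cohort_path.exists():
                raise FileNotFoundError(f"evaluate stage: cohort file {cohort_path} missing")
            df = io.read_cohort(cohort_path)
            report = evaluation.run_full_evaluation(
                df, seed=config.seed, split_sizes=config.split_sizes,
                families=config.families,
            )
            report.to_json(report_path)
            manifest.record(stage_name, {"report": report_path})
            summary["report"] = str(report_path)
            summary["best_family"] = report.best_family

    manifest.write()
    summary["manifest"] = str(manifest.path)
    return summary
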