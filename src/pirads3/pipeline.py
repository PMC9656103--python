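"""End-to-end pipeline orchestration: simulate -> extract -> select ->
evaluate, with a run manifest sufficient to re-execute bit-identically."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import LesionStudy
from .cohort_io import read_cohort, write_cohort, write_feature_matrix
from .features import extract_feature_vector
from .features.extract import core_feature_names, proposed_feature_names
from .models import (
    PROPOSED_FAMILIES,
    ClassifierSpec,
    evaluate_multivariate_cv,
    evaluate_univariate_cv,
    train_final_model,
)
from .preprocess import get_preset
from .selection import make_splits, run_stability_selection
from .synthetic import CohortSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "build_feature_matrix"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run; serialized verbatim into the
    manifest."""

    out_dir: str
    cohort_dir: str | None = None  # read an existing cohort if given
    preset: str = "proposed"
    feature_set: str = "core"  # core | full
    n_repetitions: int = 100
    n_folds: int = 5
    p_cutoff: float = 0.01
    rho_cutoff: float = 0.5
    rate_cutoff: float = 0.8
    pool_size: int = 3
    families: tuple[str, ...] = PROPOSED_FAMILIES
    seed: int = 17
    write_cohort_files: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class RunManifest:
    config: dict
    versions: dict
    stages: dict = field(default_factory=dict)
    warnings: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def checksum(self, path: Path) -> None:
        self.artifacts[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, default=str))


def build_feature_matrix(
    studies: list[LesionStudy],
    preset_name: str = "proposed",
    feature_set: str = "core",
    warnings: list[str] | None = None,
) -> pd.DataFrame:
    """Clinical + radiomic feature matrix (patients x named features)."""
    preset = get_preset(preset_name)
    include = None
    if preset_name == "proposed" and feature_set == "core":
        include = core_feature_names()
    rows, index = [], []
    for study in studies:
        row = dict(study.clinical.features())
        row.update(extract_feature_vector(study, preset, include=include, warnings=warnings))
        rows.append(row)
        index.append(study.clinical.patient_id)
    return pd.DataFrame(rows, index=index)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages, writing artifacts to ``config.out_dir``.

    Artifacts: cohort files (optional), ``features.csv`` (+ JSON sidecar),
    ``selection_rates.csv``, ``cv_reports.json``, ``per_trial_metrics.csv``,
    ``final_model.json`` and ``manifest.json``. Idempotent for identical
    config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=asdict(config),
        versions={"pirads3": __version__, "numpy": np.__version__},
    )
    warnings: list[str] = []

    def stage(name):
        t0 = time.time()

        def done():
            manifest.stages[name] = {"seconds": round(time.time() - t0, 3)}
            logger.info("stage %s finished in %.1fs", name, time.time() - t0)

        return done

    # ---- cohort ----
    done = stage("cohort")
    if config.cohort_dir is not None:
        studies = read_cohort(config.cohort_dir)
    else:
        studies = generate_cohort(CohortSpec(seed=config.seed))
        if config.write_cohort_files:
            write_cohort(studies, out / "cohort")
    labels = np.array([s.clinical.label for s in studies])
    done()

    # ---- features ----
    done = stage("extract")
    features = build_feature_matrix(
        studies, config.preset, config.feature_set, warnings=warnings
    )
    fpath = out / "features.csv"
    write_feature_matrix(
        features,
        fpath,
        sidecar={
            "preset": config.preset,
            "feature_set": config.feature_set,
            "seed": config.seed,
            "version": __version__,
        },
    )
    manifest.checksum(fpath)
    done()

    # ---- selection ----
    done = stage("select")
    splits = make_splits(labels, config.n_repetitions, config.n_folds, config.seed)
    result = run_stability_selection(
        features, labels, splits, p_cutoff=config.p_cutoff, rho_cutoff=config.rho_cutoff
    )
    spath = out / "selection_rates.csv"
    result.to_frame().to_csv(spath, index=False)
    manifest.checksum(spath)
    pool = result.final_pool(config.rate_cutoff)[: config.pool_size]
    if not pool:  # fall back to the top-ranked features
        pool = [name for name, _ in result.ranked()[: config.pool_size]]
    manifest.stages["select_pool"] = {"pool": pool}
    done()

    # ---- evaluation ----
    done = stage("evaluate")
    reports = []
    for feat in pool:
        reports.append(
            evaluate_univariate_cv(
                features[feat].to_numpy(dtype=float), labels, splits, feature=feat
            )
        )
    specs = [ClassifierSpec(family=f) for f in config.families]
    reports += evaluate_multivariate_cv(
        features, labels, splits, specs, pool, seed=config.seed
    )
    cpath = out / "cv_reports.json"
    cpath.write_text(json.dumps([r.summary() for r in reports], indent=2))
    manifest.checksum(cpath)
    trial_rows = []
    for r in reports:
        for t in range(r.n_trials):
            trial_rows.append(
                {
                    "model": r.model,
                    "features": "+".join(r.features),
                    "trial": t,
                    "sensitivity": r.sensitivity[t],
                    "specificity": r.specificity[t],
                }
            )
    tpath = out / "per_trial_metrics.csv"
    pd.DataFrame(trial_rows).to_csv(tpath, index=False)
    manifest.checksum(tpath)
    manifest.stages["evaluate_counts"] = {
        "n_reports": len(reports),
        "n_univariate": len(pool),
        "n_multivariate": len(reports) - len(pool),
        "n_families": len(specs),
        "n_subsets": (2 ** len(pool)) - 1,
    }
    done()

    # ---- final model ----
    done = stage("final_model")
    best_multi = max(
        (r for r in reports if len(r.features) > 1 or r.model != f"youden[{r.features[0]}]"),
        key=lambda r: r.mean_youden,
        default=None,
    )
    final_spec = ClassifierSpec(family="linear_discriminant")
    try:
        final = train_final_model(features, labels, final_spec, pool)
        mpath = out / "final_model.json"
        final.to_json(mpath)
        manifest.checksum(mpath)
    except ValueError as exc:
        warnings.append(f"final model not serialized: {exc}")
    if best_multi is not None:
        manifest.stages["best_multivariate"] = best_multi.summary()
    done()

    manifest.warnings = {"degenerate_features": warnings, "count": len(warnings)}
    manifest.save(out / "manifest.json")
    return manifest
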