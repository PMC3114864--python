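"""End-to-end pipeline runs with a YAML config and a reproducible manifest.

A single config drives every stage: simulate (or ingest) a cohort, grade
it, optionally screen features, cluster, scan cutoffs, and write the
report files. Every run is fully determined by (config, seed); the
manifest records the config snapshot, seeds, version, input hashes, stage
timings and all output paths.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort_io import read_cohort_csv, write_cohort_csv
from .cutoff import COARSE_GRID, FINE_STEP
from .feature_select import (
    SupervisedDataset,
    cv_auroc,
    dichotomize_outcome,
    train_blr_laplace,
    train_linear_svm,
)
from .grading import default_scheme, scheme_from_yaml
from .model import HomaCutoffModel
from .synthetic import GeneratorConfig, generate_cohort

__all__ = ["RunManifest", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_hashes: dict[str, str]
    stage_seconds: dict[str, float]
    outputs: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True, default=str)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _resolve_scheme(config: dict):
    sch = config.get("scheme", "default")
    if sch == "default":
        return default_scheme(include_fpi=bool(config.get("include_fpi", False)))
    return scheme_from_yaml(Path(sch).read_text())


def run_pipeline(config: dict, out_dir, seed: int = 0) -> RunManifest:
    """Run every stage and write all report files under ``out_dir``.

    Config keys (all optional): ``input_csv`` (ingest instead of
    simulating), ``generator`` (kwargs of GeneratorConfig), ``scheme``
    ("default" or path to a YAML scheme), ``include_fpi``, ``n_restarts``,
    ``grid`` [start, stop, step], ``fine_step``, ``band_low``,
    ``feature_selection`` ({method, C, prior_scale, folds}).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    outputs: dict[str, str] = {}
    input_hashes: dict[str, str] = {}

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 4)
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _T()

    # --- simulate or ingest -------------------------------------------------
    with _stage("cohort"):
        if "input_csv" in config:
            src = Path(config["input_csv"])
            input_hashes[str(src)] = _sha256(src)
            cohort, rejects = read_cohort_csv(src, column_map=config.get("column_map"))
            truth = None
        else:
            gen = GeneratorConfig(**{**config.get("generator", {}), "seed": seed})
            cohort, truth = generate_cohort(gen)
            cohort_path = out / "cohort.csv"
            write_cohort_csv(cohort, cohort_path)
            outputs["cohort"] = str(cohort_path)
            truth_path = out / "truth.csv"
            pd.DataFrame(
                {
                    "subject_id": cohort.df["subject_id"],
                    "latent_label": truth.latent_label,
                }
            ).to_csv(truth_path, index=False)
            outputs["truth"] = str(truth_path)

    # --- grade + cluster + scan via the model object ------------------------
    with _stage("fit"):
        scheme = _resolve_scheme(config)
        model = HomaCutoffModel(
            cohort,
            scheme=scheme,
            grid=tuple(config.get("grid", COARSE_GRID)),
            fine_step=float(config.get("fine_step", FINE_STEP)),
            band_low=float(config.get("band_low", 2.60)),
        )
        res = model.fit(n_restarts=int(config.get("n_restarts", 50)), seed=seed)

    # --- optional supervised screening --------------------------------------
    fs_report = None
    if config.get("feature_selection"):
        with _stage("feature_selection"):
            fs = config["feature_selection"]
            candidates = [v for v in scheme.variables if v != "fpi"] + ["age"]
            keep = cohort.df["subject_id"].astype(str).isin(set(res.graded.subject_ids))
            sub = cohort.df.loc[keep]
            x = sub[candidates].to_numpy(dtype=float)
            y = dichotomize_outcome(sub["homa_ir"].to_numpy(dtype=float))
            data = SupervisedDataset.from_raw(x, y, candidates)
            method = fs.get("method", "blr")
            if method == "svm":
                trainer = lambda d: train_linear_svm(d, C=float(fs.get("C", 1.0)), seed=seed)
            else:
                trainer = lambda d: train_blr_laplace(
                    d, prior_scale=float(fs.get("prior_scale", 1.0))
                )
            ranking = trainer(data)
            auroc = cv_auroc(data, trainer, k_folds=int(fs.get("folds", 5)), seed=seed)
            fs_frame = pd.DataFrame(
                {"variable": ranking.variables, "weight": ranking.weights}
            ).sort_values("weight", key=np.abs, ascending=False)
            fs_path = out / "feature_ranking.csv"
            fs_frame.to_csv(fs_path, index=False)
            outputs["feature_ranking"] = str(fs_path)
            fs_report = {"method": method, "cv_auroc": auroc}

    # --- reports -------------------------------------------------------------
    with _stage("report"):
        res.scan_frame().to_csv(out / "scan_coarse.csv", index=False)
        res.scan_frame(fine=True).to_csv(out / "scan_fine.csv", index=False)
        res.anova_frame().to_csv(out / "cluster_report.csv", index=False)
        res.assignment_frame().to_csv(out / "assignment.csv", index=False)
        pd.DataFrame({"fpr": res.roc.fpr, "tpr": res.roc.tpr}).to_csv(
            out / "roc.csv", index=False
        )
        summary = {
            "n_subjects": len(res.graded.subject_ids),
            "n_excluded": res.graded.n_excluded,
            "n_resistant": res.assignment.n_resistant,
            "n_control": res.assignment.n_control,
            "best_cutoff": res.cutoff,
            "best_mcc": res.mcc,
            "sensitivity": res.cutoff_row.sensitivity,
            "specificity": res.cutoff_row.specificity,
            "fine_cutoff": res.fine_cutoff,
            "fine_mcc": res.fine_cutoff_row.mcc,
            "roc_auc": res.auc,
            "bands": res.bands,
        }
        if truth is not None:
            summary["oracle_cutoff"] = truth.oracle_cutoff
            agree = float(
                np.mean(res.assignment.is_resistant.astype(int) == truth.latent_label)
            )
            summary["latent_agreement"] = max(agree, 1.0 - agree)
        if fs_report is not None:
            summary["feature_selection"] = fs_report
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        for name in (
            "scan_coarse",
            "scan_fine",
            "cluster_report",
            "assignment",
            "roc",
        ):
            outputs[name] = str(out / f"{name}.csv")
        outputs["summary"] = str(out / "summary.json")

    manifest = RunManifest(
        config=config,
        seed=seed,
        version=__version__,
        input_hashes=input_hashes,
        stage_seconds=timings,
        outputs=outputs,
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
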