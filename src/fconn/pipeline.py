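"""End-to-end pipeline: cohort -> FC matrices -> embeddings -> CV reports.

One flat INI-style config file drives the whole run.  Every random draw
traces back to the single top-level seed through documented per-stage
derived seeds (CRC-32 of the stage name mixed into the seed), so stages can
be re-run in isolation and a full re-run with the same config reproduces
all numeric outputs bit-identically.  Report JSON files carry no
timestamps; wall-clock timings go to ``run.log`` only.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import embedding as emb_mod
from . import evaluation as eval_mod
from . import fc as fc_mod
from . import melm as melm_mod
from .errors import ValidationError

logger = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


# ---------------------------------------------------------------------------
# config schema: section -> {key: (type, default)}; None default = required

_SCHEMA: dict[str, dict[str, tuple]] = {
    "cohort": {
        "input_dir": (str, ""),
        "n_per_group": (int, 20),
        "labels": (str, "CN,MCI,AD"),
        "n_rois": (int, 30),
        "n_timepoints": (int, 140),
        "tr_seconds": (float, 3.0),
        "band_low": (float, 0.01),
        "band_high": (float, 0.08),
        "noise_sd": (float, 1.0),
        "n_linear_edges": (int, 5),
        "linear_strength": (float, 0.8),
        "n_nonlinear_edges": (int, 10),
        "nonlinear_strengths": (str, "CN:0.4,MCI:1.0,AD:1.6"),
    },
    "measures": {"use": (str, "PCC,MIC,eMIC")},
    "embedding": {
        "dimensions": (int, 16),
        "walk_length": (int, 40),
        "walks_per_node": (int, 10),
        "window": (int, 5),
        "p": (float, 1.0),
        "q": (float, 1.0),
        "epochs": (int, 5),
        "negative_samples": (int, 5),
        "learning_rate": (float, 0.1),
        "sparsify_top_fraction": (float, 1.0),
        # flattened-FC features are the default: at desk scale the per-subject
        # skip-gram training noise exceeds between-group embedding differences
        "feature_mode": (str, "fc_flatten"),
    },
    "classifier": {
        "n_layers": (int, 3),
        "neurons_per_layer": (str, "334,333,333"),
        "activation": (str, "sigmoid"),
        "ridge_lambda": (float, 1e-6),
        "layer_mode": (str, "parallel"),
    },
    "evaluation": {
        "tasks": (str, "CN-AD"),
        "n_features_grid": (str, "64"),
        "k_folds": (int, 10),
    },
    "run": {"seed": (int, None)},
}


@dataclass
class PipelineConfig:
    raw: dict[str, dict[str, object]]

    def __getitem__(self, section: str) -> dict:
        return self.raw[section]

    @property
    def seed(self) -> int:
        return self.raw["run"]["seed"]

    @property
    def measures(self) -> list[str]:
        return [m.strip() for m in self.raw["measures"]["use"].split(",") if m.strip()]

    @property
    def tasks(self) -> list[tuple[str, str]]:
        out = []
        for item in self.raw["evaluation"]["tasks"].split(","):
            item = item.strip()
            if not item:
                continue
            parts = item.split("-")
            if len(parts) != 2:
                raise ValidationError(f"evaluation.tasks: bad task {item!r}")
            out.append((parts[0].strip(), parts[1].strip()))
        return out

    def node2vec_config(self, seed: int) -> emb_mod.Node2VecConfig:
        e = self.raw["embedding"]
        return emb_mod.Node2VecConfig(
            dimensions=e["dimensions"], walk_length=e["walk_length"],
            walks_per_node=e["walks_per_node"], window=e["window"],
            p=e["p"], q=e["q"], epochs=e["epochs"],
            negative_samples=e["negative_samples"],
            learning_rate=e["learning_rate"], seed=seed,
        )

    def melm_config(self, seed: int) -> melm_mod.MELMConfig:
        c = self.raw["classifier"]
        return melm_mod.MELMConfig(
            n_layers=c["n_layers"],
            neurons_per_layer=tuple(
                int(v) for v in str(c["neurons_per_layer"]).split(",")
            ),
            activation=c["activation"], ridge_lambda=c["ridge_lambda"],
            layer_mode=c["layer_mode"], seed=seed,
        )

    def cohort_spec(self) -> cohort_mod.CohortSpec:
        c = self.raw["cohort"]
        labels = tuple(v.strip() for v in c["labels"].split(",") if v.strip())
        strengths = {}
        for item in c["nonlinear_strengths"].split(","):
            item = item.strip()
            if not item:
                continue
            if ":" not in item:
                raise ValidationError(
                    "cohort.nonlinear_strengths: expected LABEL:value entries"
                )
            lab, val = item.split(":", 1)
            strengths[lab.strip()] = float(val)
        return cohort_mod.default_contrast_spec(
            n_per_group=c["n_per_group"], labels=labels, n_rois=c["n_rois"],
            n_timepoints=c["n_timepoints"], tr_seconds=c["tr_seconds"],
            band=(c["band_low"], c["band_high"]), noise_sd=c["noise_sd"],
            n_linear_edges=c["n_linear_edges"],
            linear_strength=c["linear_strength"],
            n_nonlinear_edges=c["n_nonlinear_edges"],
            nonlinear_strengths={g: strengths[g] for g in labels},
            seed=stage_seed(self.seed, "cohort"),
        )

    def normalized_text(self) -> str:
        lines = []
        for section in sorted(self.raw):
            lines.append(f"[{section}]")
            for key in sorted(self.raw[section]):
                lines.append(f"{key} = {self.raw[section][key]}")
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        return hashlib.sha256(self.normalized_text().encode()).hexdigest()


def example_config() -> str:
    lines = []
    for section, keys in _SCHEMA.items():
        lines.append(f"[{section}]")
        for key, (_, default) in keys.items():
            lines.append(f"{key} = {0 if default is None else default}")
        lines.append("")
    return "\n".join(lines)


def _validate_values(cfg: PipelineConfig) -> None:
    c = cfg.raw["cohort"]
    if c["noise_sd"] <= 0:
        raise ValidationError("cohort.noise_sd: must be positive")
    if not (0 <= c["band_low"] < c["band_high"]):
        raise ValidationError("cohort.band_low must be < band_high")
    for m in cfg.measures:
        if m not in fc_mod.MEASURES:
            raise ValidationError(f"measures.use: unknown measure {m!r}")
    if not cfg.measures:
        raise ValidationError("measures.use: need at least one measure")
    if not cfg.tasks:
        raise ValidationError("evaluation.tasks: need at least one task")
    fm = cfg.raw["embedding"]["feature_mode"]
    if fm not in ("node2vec", "fc_flatten"):
        raise ValidationError(
            f"embedding.feature_mode: {fm!r} not in (node2vec, fc_flatten)"
        )
    frac = cfg.raw["embedding"]["sparsify_top_fraction"]
    if not (0 < frac <= 1):
        raise ValidationError("embedding.sparsify_top_fraction: must be in (0, 1]")
    grid = cfg.raw["evaluation"]["n_features_grid"]
    if grid != "all":
        try:
            vals = [int(v) for v in grid.split(",")]
        except ValueError as exc:
            raise ValidationError(
                "evaluation.n_features_grid: expected 'all' or comma-separated ints"
            ) from exc
        if any(v < 1 for v in vals):
            raise ValidationError("evaluation.n_features_grid: counts must be >= 1")
    if cfg.raw["evaluation"]["k_folds"] < 2:
        raise ValidationError("evaluation.k_folds: must be >= 2")
    # instantiating sub-configs validates their own ranges
    cfg.node2vec_config(seed=0)
    cfg.melm_config(seed=0)


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, check against the schema (unknown keys rejected), fill defaults."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config file not found: {path}")
    parser = configparser.ConfigParser()
    parser.read(path)
    raw: dict[str, dict[str, object]] = {}
    for section in parser.sections():
        if section not in _SCHEMA:
            raise ValidationError(f"unknown config section [{section}]")
        raw[section] = {}
        for key, value in parser.items(section):
            if key not in _SCHEMA[section]:
                raise ValidationError(f"unknown config key {section}.{key}")
            typ, _ = _SCHEMA[section][key]
            try:
                raw[section][key] = typ(value)
            except ValueError as exc:
                raise ValidationError(
                    f"config key {section}.{key}: cannot parse {value!r} as "
                    f"{typ.__name__}"
                ) from exc
    for section, keys in _SCHEMA.items():
        raw.setdefault(section, {})
        for key, (typ, default) in keys.items():
            if key not in raw[section]:
                if default is None:
                    raise ValidationError(f"missing required config key {section}.{key}")
                raw[section][key] = default
    cfg = PipelineConfig(raw=raw)
    _validate_values(cfg)
    return cfg


# ---------------------------------------------------------------------------
# stages


def stage_generate(cfg: PipelineConfig, out_dir: Path) -> cohort_mod.LabeledCohort:
    input_dir = cfg.raw["cohort"]["input_dir"]
    if input_dir:
        cohort = cohort_mod.read_cohort(input_dir)
    else:
        cohort = cohort_mod.generate_cohort(cfg.cohort_spec())
    cohort_mod.write_cohort(cohort, out_dir / "cohort")
    return cohort


def stage_fc(cfg: PipelineConfig, cohort: cohort_mod.LabeledCohort,
             out_dir: Path) -> dict[str, dict[str, fc_mod.FCMatrix]]:
    """measure -> subject_id -> FCMatrix, persisted as TSV."""
    fc_dir = out_dir / "fc"
    result: dict[str, dict[str, fc_mod.FCMatrix]] = {m: {} for m in cfg.measures}
    for subj in cohort.subjects:
        mats = fc_mod.all_fc_matrices(subj, cfg.measures)
        for m in cfg.measures:
            result[m][subj.subject_id] = mats[m]
            fc_mod.write_fc_matrix(mats[m], fc_dir)
    return result


def stage_embed(cfg: PipelineConfig, fcs: dict[str, dict[str, fc_mod.FCMatrix]],
                cohort: cohort_mod.LabeledCohort,
                out_dir: Path) -> dict[str, pd.DataFrame]:
    """measure -> features DataFrame (rows = subjects, fixed column order).

    All subjects are embedded with the same derived seed: identical graphs
    then yield identical feature vectors, and differences between feature
    vectors reflect differences between graphs.
    """
    feat_dir = out_dir / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    mode = cfg.raw["embedding"]["feature_mode"]
    frac = cfg.raw["embedding"]["sparsify_top_fraction"]
    n2v = cfg.node2vec_config(seed=stage_seed(cfg.seed, "embed"))
    out: dict[str, pd.DataFrame] = {}
    subject_ids = [s.subject_id for s in cohort.subjects]
    for measure, per_subject in fcs.items():
        rows = []
        for sid in subject_ids:
            fc = per_subject[sid]
            if mode == "fc_flatten":
                rows.append(emb_mod.fc_flatten_features(fc))
            else:
                graph = emb_mod.fc_to_graph(fc, frac)
                emb = emb_mod.embed_graph(graph, n2v, sid)
                rows.append(emb_mod.subject_features(emb, fc.roi_labels))
        df = pd.DataFrame(np.vstack(rows), index=subject_ids)
        df.to_csv(feat_dir / f"{measure}.features.tsv", sep="\t", header=False,
                  float_format="%.17g")
        out[measure] = df
    return out


def stage_classify(cfg: PipelineConfig, features: dict[str, pd.DataFrame],
                   cohort: cohort_mod.LabeledCohort,
                   out_dir: Path) -> list[eval_mod.CVReport]:
    rep_dir = out_dir / "reports"
    rep_dir.mkdir(parents=True, exist_ok=True)
    cv_seed = stage_seed(cfg.seed, "classify")
    melm_cfg = cfg.melm_config(seed=stage_seed(cfg.seed, "melm"))
    k_folds = cfg.raw["evaluation"]["k_folds"]
    grid_spec = cfg.raw["evaluation"]["n_features_grid"]
    reports: list[eval_mod.CVReport] = []
    summary_rows = []
    for task in cfg.tasks:
        for measure in cfg.measures:
            df = features[measure]
            labels = [cohort.labels[sid] for sid in df.index]
            dim = df.shape[1]
            grid = [dim] if grid_spec == "all" else [
                min(int(v), dim) for v in grid_spec.split(",")
            ]
            reps = eval_mod.run_cv(
                df.to_numpy(float), labels, task, measure, grid, melm_cfg,
                seed=cv_seed, k_folds=k_folds,
            )
            reports.extend(reps)
            task_name = f"{task[0]}_vs_{task[1]}"
            payload = {
                "task": task_name, "measure": measure,
                "config_hash": cfg.config_hash(),
                "reports": [r.to_dict() for r in reps],
            }
            (rep_dir / f"{task_name}.{measure}.json").write_text(
                json.dumps(payload, indent=2, sort_keys=True) + "\n"
            )
            for r in reps:
                summary_rows.append({
                    "task": task_name, "measure": measure,
                    "n_features": r.n_features, "accuracy": r.accuracy,
                    "sensitivity": r.sensitivity, "specificity": r.specificity,
                })
    pd.DataFrame(summary_rows).to_csv(rep_dir / "summary.tsv", sep="\t",
                                      index=False, float_format="%.6g")
    return reports


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute all stages; returns the run manifest (also written to disk)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("fconn")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    stages = ("generate", "fc", "embed", "classify")
    timings = {}
    current = "generate"
    try:
        t0 = time.perf_counter()
        cohort = stage_generate(cfg, out_dir)
        timings["generate"] = time.perf_counter() - t0

        current = "fc"
        t0 = time.perf_counter()
        fcs = stage_fc(cfg, cohort, out_dir)
        timings["fc"] = time.perf_counter() - t0

        current = "embed"
        t0 = time.perf_counter()
        features = stage_embed(cfg, fcs, cohort, out_dir)
        timings["embed"] = time.perf_counter() - t0

        current = "classify"
        t0 = time.perf_counter()
        reports = stage_classify(cfg, features, cohort, out_dir)
        timings["classify"] = time.perf_counter() - t0
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {current}: {exc}\n")
        root.error("stage %s failed: %s", current, exc)
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    for stage, dt in timings.items():
        logger.info("stage %s: %.2fs", stage, dt)
    manifest = {
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "stage_seeds": {s: stage_seed(cfg.seed, s)
                        for s in ("cohort", "embed", "melm", "classify")},
        "n_subjects": len(cohort.subjects),
        "measures": cfg.measures,
        "tasks": [f"{a}_vs_{b}" for a, b in cfg.tasks],
        "n_reports": len(reports),
        "stages": list(stages),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "run.log").touch()
    return manifest
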