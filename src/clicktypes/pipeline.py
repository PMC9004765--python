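"""End-to-end orchestration: simulate → detect → featurize → cluster → train
→ classify → evaluate.

Each stage reads the previous stage's files from the run directory and
writes self-describing CSV tables, so stages can also be run standalone.  A
manifest records the configuration hash, the global seed and per-stage row
counts; re-running an identical configuration reproduces an identical
manifest.  All stage randomness is seeded deterministically from the global
seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from clicktypes import synth
from clicktypes.classifier import (
    NetworkConfig,
    build_training_set,
    classify_bins,
    train_network,
)
from clicktypes.clustering import ClusterParams, cluster_bin, cluster_types, match_templates
from clicktypes.detection import DetectorParams, detect_clicks, detections_to_frame
from clicktypes.evaluation import class_metrics, confusion_matrix, relative_presence
from clicktypes.features import assign_bins, bin_cluster_frame
from clicktypes.network import DropoutMLP
from clicktypes.templates import template

__all__ = ["DeploymentSpec", "PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "detect", "featurize", "cluster", "train", "classify", "evaluate")


@dataclass(frozen=True)
class DeploymentSpec:
    """One synthetic deployment: trains of named click types in one recording."""

    name: str
    duration_s: float
    #: (template name, start_s, n_clicks, rl_lo_dbpp, rl_hi_dbpp)
    trains: tuple[tuple[str, float, int, float, float], ...]


@dataclass(frozen=True)
class PipelineConfig:
    """Serializable configuration of a full pipeline run."""

    deployments: tuple[DeploymentSpec, ...]
    fs_hz: int = 200_000
    background_rms: float = 1.0
    calibration_db: float = 60.0
    detector: DetectorParams = field(default_factory=DetectorParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    #: labelled bins per class generated for classifier training
    train_bins_per_class: int = 200
    seed: int = 0

    def template_names(self) -> list[str]:
        names: list[str] = []
        for dep in self.deployments:
            for t in dep.trains:
                if t[0] not in names:
                    names.append(t[0])
        return names

    def to_dict(self) -> dict:
        d = asdict(self)
        d["deployments"] = [asdict(dep) for dep in self.deployments]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        deployments = tuple(
            DeploymentSpec(
                name=dep["name"],
                duration_s=float(dep["duration_s"]),
                trains=tuple(tuple(t) for t in dep["trains"]),
            )
            for dep in d.pop("deployments")
        )
        for key, typ in (("detector", DetectorParams), ("cluster", ClusterParams),
                         ("network", NetworkConfig)):
            if key in d and isinstance(d[key], dict):
                block = d[key]
                for tup_key in ("hidden_layers", "split"):
                    if tup_key in block:
                        block[tup_key] = tuple(block[tup_key])
                d[key] = typ(**block)
        return cls(deployments=deployments, **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    h = hashlib.sha256(f"{config.seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _scene_for(config: PipelineConfig, dep: DeploymentSpec, seed: int) -> synth.SceneConfig:
    trains = tuple(
        synth.TrainSpec(template=template(name), start_s=start, n_clicks=n,
                        rl_range_dbpp=(lo, hi))
        for name, start, n, lo, hi in dep.trains
    )
    return synth.SceneConfig(
        fs_hz=config.fs_hz,
        duration_s=dep.duration_s,
        trains=trains,
        noise=synth.NoiseSpec(background_rms=config.background_rms),
        calibration_db=config.calibration_db,
        seed=seed,
    )


def stage_simulate(config: PipelineConfig, rundir: Path) -> dict:
    seed0 = _stage_seed(config, "simulate")
    counts = {}
    for i, dep in enumerate(config.deployments):
        audio, truth = synth.render_scene(_scene_for(config, dep, seed0 + i))
        synth.write_scene_wav(rundir / f"scene_{dep.name}.wav", audio, config.fs_hz)
        truth.to_csv(rundir / f"truth_{dep.name}.csv", index=False)
        counts[dep.name] = len(truth)
    return counts


def stage_detect(config: PipelineConfig, rundir: Path) -> dict:
    from scipy.io import wavfile

    counts = {}
    for dep in config.deployments:
        _, audio = wavfile.read(rundir / f"scene_{dep.name}.wav")
        dets = detect_clicks(audio.astype(float), config.fs_hz, config.detector,
                             config.calibration_db, source_file=dep.name)
        detections_to_frame(dets).to_csv(rundir / f"detections_{dep.name}.csv", index=False)
        counts[dep.name] = len(dets)
    return counts


def stage_featurize(config: PipelineConfig, rundir: Path) -> dict:
    rng = np.random.default_rng(_stage_seed(config, "featurize"))
    counts = {}
    for dep in config.deployments:
        dets = pd.read_csv(rundir / f"detections_{dep.name}.csv")
        clusters = []
        for bin_start, idx in sorted(assign_bins(dets).items()):
            clusters.extend(
                cluster_bin(dets.loc[idx], config.cluster, rng, bin_start=bin_start)
            )
        frame = bin_cluster_frame(clusters)
        frame.insert(0, "deployment", dep.name)
        frame.to_csv(rundir / f"binfeatures_{dep.name}.csv", index=False)
        counts[dep.name] = len(frame)
    return counts


def _load_bin_features(config: PipelineConfig, rundir: Path) -> pd.DataFrame:
    frames = [
        pd.read_csv(rundir / f"binfeatures_{dep.name}.csv")
        for dep in config.deployments
    ]
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

def _frame_to_clusters(frame: pd.DataFrame):
    from clicktypes.features import BinCluster

    spec_cols = [c for c in frame.columns if c.startswith("spec_")]
    ici_cols = [c for c in frame.columns if c.startswith("ici_")]
    env_cols = [c for c in frame.columns if c.startswith("env_")]
    return [
        BinCluster(
            bin_start=float(row["bin_start"]),
            cluster_id=int(row["cluster_id"]),
            member_count=int(row["member_count"]),
            mean_spectrum=row[spec_cols].to_numpy(dtype=float),
            ici_hist=row[ici_cols].to_numpy(dtype=float),
            mean_envelope=row[env_cols].to_numpy(dtype=float),
            modal_ici_s=float(row["modal_ici_s"]),
            rl_max_dbpp=float(row["rl_max_dbpp"]),
        )
        for _, row in frame.iterrows()
    ]


def stage_cluster(config: PipelineConfig, rundir: Path) -> dict:
    features = _load_bin_features(config, rundir)
    clusters = _frame_to_clusters(features)
    rng = np.random.default_rng(_stage_seed(config, "cluster"))
    groups = cluster_types(clusters, config.cluster, rng)
    assignments = match_templates(groups, [template(n) for n in config.template_names()])
    id_of = {}
    for gi, group in enumerate(groups):
        for c in group:
            id_of[(c.bin_start, c.cluster_id)] = (gi, assignments[gi])
    rows = []
    for _, row in features.iterrows():
        key = (float(row["bin_start"]), int(row["cluster_id"]))
        gi, label = id_of.get(key, (-1, "unassigned"))
        rows.append({"deployment": row["deployment"], "bin_start": key[0],
                     "cluster_id": key[1], "type_cluster": gi, "type_label": label})
    pd.DataFrame(rows).to_csv(rundir / "type_assignments.csv", index=False)
    summary = {"n_type_clusters": len(groups), "labels": assignments}
    (rundir / "type_summary.json").write_text(json.dumps(summary, indent=2))
    return {"type_clusters": len(groups)}


def stage_train(config: PipelineConfig, rundir: Path) -> dict:
    labelled = synth.synth_labelled_bins(
        [template(n) for n in config.template_names()],
        n_bins_per_class=config.train_bins_per_class,
        seed=_stage_seed(config, "train"),
        fs_hz=config.fs_hz,
    )
    rng = np.random.default_rng(_stage_seed(config, "train") + 1)
    sets = build_training_set(labelled, config.network, rng)
    model = train_network(sets, config.network)
    model.save(rundir / "model.npz")
    return {"classes": len(sets.classes), "train_examples": len(sets.train)}


def stage_classify(config: PipelineConfig, rundir: Path) -> dict:
    model = DropoutMLP.load(rundir / "model.npz")
    features = _load_bin_features(config, rundir)
    labels = classify_bins(model, features)
    labels.insert(0, "deployment", features["deployment"])
    labels.to_csv(rundir / "labels.csv", index=False)
    return {"labelled_bins": len(labels)}


def _truth_label_of_bins(config: PipelineConfig, rundir: Path) -> pd.DataFrame:
    """Majority true click type per (deployment, bin) from the ground truth."""
    rows = []
    for dep in config.deployments:
        truth = pd.read_csv(rundir / f"truth_{dep.name}.csv")
        if truth.empty:
            continue
        truth["bin_start"] = (truth["time_s"] // 300.0) * 300.0
        for bin_start, grp in truth.groupby("bin_start"):
            rows.append({"deployment": dep.name, "bin_start": float(bin_start),
                         "true_label": grp["type"].mode().iloc[0]})
    return pd.DataFrame(rows, columns=["deployment", "bin_start", "true_label"])


def stage_evaluate(config: PipelineConfig, rundir: Path) -> dict:
    labels = pd.read_csv(rundir / "labels.csv")
    truth = _truth_label_of_bins(config, rundir)
    merged = labels.merge(truth, on=["deployment", "bin_start"], how="inner")
    class_order = sorted(set(config.template_names()) | {synth.JUNK_CLASS}
                         | set(merged["label"].unique()))
    matrix = confusion_matrix(merged["true_label"], merged["label"], class_order)
    metrics = pd.DataFrame(
        [
            {
                "class": cls,
                "accuracy": m.accuracy,
                "recall": m.recall,
                "precision": m.precision,
                "specificity": m.specificity,
                "n_bins": m.n_bins,
            }
            for cls in class_order
            for m in [class_metrics(matrix, cls)]
        ]
    )
    matrix.to_frame().to_csv(rundir / "confusion.csv")
    metrics.to_csv(rundir / "metrics.csv", index=False)
    # desk-scale presence: each synthetic deployment counts as one recording day
    bins = labels.copy()
    bins["day"] = 0
    presence = relative_presence(bins, {d.name: 1 for d in config.deployments})
    presence.to_csv(rundir / "presence.csv", index=False)
    return {"evaluated_bins": len(merged)}


_STAGE_FN = {
    "simulate": stage_simulate,
    "detect": stage_detect,
    "featurize": stage_featurize,
    "cluster": stage_cluster,
    "train": stage_train,
    "classify": stage_classify,
    "evaluate": stage_evaluate,
}


def run_stage(name: str, config: PipelineConfig, rundir: str | Path) -> dict:
    """Run one named stage in ``rundir``; returns its count summary."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    try:
        return _STAGE_FN[name](config, rundir)
    except KeyError:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}") from None
    except Exception as exc:
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: PipelineConfig, rundir: str | Path) -> dict:
    """Run every stage in order and write a reproducible manifest."""
    rundir = Path(rundir)
    rundir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    for name in STAGES:
        manifest["stages"][name] = run_stage(name, config, rundir)
    manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(manifest, sort_keys=True).encode()
    ).hexdigest()[:16]
    (rundir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
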