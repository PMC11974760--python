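"""End-to-end orchestration: simulate -> collapse -> similarity -> persistence
-> classify -> report.

Every stage writes TSV outputs plus a plain-text summary into the output
directory, and a JSON manifest records the configuration hash, seed, package
version and per-stage record counts, so a run is reproducible byte-for-byte
from its config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .errors import PipelineStageError, ValidationError
from .io import read_rearrangements, write_rearrangements, export_fasta
from .clonotypes import collapse
from .similarity import pairwise_matrix, cluster_replicates, stratified_similarity
from .persistence import persistence_report, sharing_vs_depth, characterize_persistent, persistent_public
from .classify import evaluate_loro
from .simulate import SimulationConfig, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a full run needs; serializable to/from YAML."""

    out_dir: str = "repdrift_out"
    input_path: Optional[str] = None          # existing rearrangement TSV, or None to simulate
    simulation: Optional[SimulationConfig] = None
    seed: int = 0
    depth_grid: list = field(default_factory=lambda: [10, 100, 1000, 10000])
    n_boot: int = 20
    size_grid: list = field(default_factory=lambda: [10, 50, 100, 500, 1000])
    n_repeats: int = 3
    use_junction_keys: bool = False
    cluster_metric: str = "euclidean"
    weight_by_duplicates: bool = False
    joint_features: bool = False
    persistent_public_mode: str = "all"
    export_fasta: bool = False

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # identity is the analysis, not where it is written
        return hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if data.get("simulation") is not None:
            data["simulation"] = SimulationConfig(**data["simulation"])
        return cls(**data)


def _stage(name):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineStageError(name, exc) from exc
        return run
    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts with :class:`PipelineStageError` naming the
    stage; outputs written before the failure are flagged as partial in the
    manifest on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
        "partial": True,
    }

    def checkpoint():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    # -- acquire records --------------------------------------------------
    @_stage("input")
    def acquire():
        if config.input_path is not None:
            path = Path(config.input_path)
            if not path.exists():
                raise ValidationError(f"input path does not exist: {path}")
            records = read_rearrangements(path)
            truth = None
        else:
            sim = config.simulation or SimulationConfig(seed=config.seed)
            records, truth = simulate_study(sim)
            write_rearrangements(records, out / "rearrangements.tsv")
            truth.write(out / "ground_truth_lineages.tsv", out / "ground_truth_records.tsv")
        if config.export_fasta:
            export_fasta(records, out / "rearrangements.fasta")
        return records, truth

    records, truth = acquire()
    manifest["stages"]["input"] = {
        "n_records": len(records),
        "dropped_rows": int(records.attrs.get("dropped_rows", 0)),
        "simulated": truth is not None,
    }
    checkpoint()

    subjects = sorted(records["subject"].unique())
    timepoints = sorted(records["timepoint"].unique())

    # -- clonotype collapse ------------------------------------------------
    @_stage("collapse")
    def do_collapse():
        tables = {}
        for (subject, tp), grp in records.groupby(["subject", "timepoint"]):
            table = collapse(grp, use_junction=config.use_junction_keys)
            table.to_csv(out / f"clonotypes_{subject}_{tp}.tsv", sep="\t")
            tables[(subject, tp)] = table
        return tables

    tables = do_collapse()
    manifest["stages"]["collapse"] = {
        f"{s}_{t}": int(tab["n_sequences"].sum()) for (s, t), tab in tables.items()}
    checkpoint()

    # -- similarity --------------------------------------------------------
    @_stage("similarity")
    def do_similarity():
        samples = {f"{s}/{t}/{r}": grp
                   for (s, t, r), grp in records.groupby(["subject", "timepoint", "replicate"])}
        mat = pairwise_matrix(samples, config.weight_by_duplicates)
        mat.to_csv(out / "pairwise_morisita_horn.tsv", sep="\t")
        _, leaves = cluster_replicates(mat, metric=config.cluster_metric)
        (out / "cluster_leaf_order.txt").write_text("\n".join(leaves) + "\n")
        pairs, summary = stratified_similarity(records, weight_by_duplicates=config.weight_by_duplicates)
        pairs.to_csv(out / "stratified_similarity_pairs.tsv", sep="\t", index=False)
        summary.to_csv(out / "stratified_similarity_summary.tsv", sep="\t", index=False)
        return mat

    mat = do_similarity()
    manifest["stages"]["similarity"] = {"n_samples": int(mat.shape[0])}
    checkpoint()

    # -- persistence -------------------------------------------------------
    @_stage("persistence")
    def do_persistence():
        rows = []
        curves = []
        for subject in subjects:
            sub = records[records["subject"] == subject]
            if len(timepoints) < 2:
                continue
            t1 = sub[sub["timepoint"] == timepoints[0]]
            t2 = sub[sub["timepoint"] == timepoints[1]]
            for level in ("clonotype", "sequence"):
                rep = persistence_report(t1, t2, level=level)
                rows.append({"subject": subject, **rep.as_dict()})
            depths = [d for d in config.depth_grid if d >= 10]
            curve = sharing_vs_depth(t1, t2, depths, n_boot=config.n_boot,
                                     seed=config.seed, level="clonotype")
            curve.insert(0, "subject", subject)
            curves.append(curve)
            summary = characterize_persistent(t1, t2)
            summary.tests.to_csv(out / f"persistent_characterization_{subject}.tsv",
                                 sep="\t", index=False)
        if rows:
            pd.DataFrame(rows).to_csv(out / "persistence_reports.tsv", sep="\t", index=False)
        if curves:
            pd.concat(curves).to_csv(out / "sharing_vs_depth.tsv", sep="\t", index=False)
        pp_count = None
        if len(subjects) >= 2 and len(timepoints) >= 2:
            by_subject = {
                s: {t: records[(records["subject"] == s) & (records["timepoint"] == t)]
                    for t in timepoints}
                for s in subjects}
            pp, pp_summary = persistent_public(by_subject, mode=config.persistent_public_mode)
            (out / "persistent_public_clonotypes.txt").write_text("\n".join(sorted(pp)) + "\n")
            if len(pp_summary.tests):
                pp_summary.tests.to_csv(out / "persistent_public_tests.tsv", sep="\t", index=False)
            pp_count = len(pp)
        return rows, pp_count

    rows, pp_count = do_persistence()
    manifest["stages"]["persistence"] = {
        "n_reports": len(rows), "n_persistent_public": pp_count}
    checkpoint()

    # -- classification ----------------------------------------------------
    @_stage("classification")
    def do_classify():
        if len(subjects) * len(timepoints) < 2:
            return None
        result = evaluate_loro(records, size_grid=config.size_grid,
                               n_repeats=config.n_repeats, seed=config.seed,
                               joint_features=config.joint_features)
        result.auc_table.to_csv(out / "classification_auc.tsv", sep="\t", index=False)
        return result

    result = do_classify()
    manifest["stages"]["classification"] = {
        "ran": result is not None,
        "max_leakage": result.max_leakage if result is not None else None,
        "mean_auc": float(result.auc_table["mean_auc"].mean()) if result is not None else None,
    }

    manifest["partial"] = False
    checkpoint()

    summary_lines = [f"repdrift run (seed={config.seed}, config={manifest['config_hash']})"]
    for stage, info in manifest["stages"].items():
        summary_lines.append(f"  {stage}: {info}")
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return manifest
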