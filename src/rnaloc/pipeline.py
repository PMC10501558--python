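"""End-to-end pipeline: encode -> embed -> train -> cross-validate.

A :class:`RunConfig` (YAML-serialisable) fixes every knob; one global
seed fans out to per-stage seeds through ``stage_seed`` (CRC-32 of the
stage name XOR the global seed, modulo 2^31), so a stage re-run
standalone with its derived seed reproduces its in-pipeline output.
"""

from __future__ import annotations

import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from rnaloc.distance import distance_matrix
from rnaloc.io import (
    read_fasta,
    read_ppi_edges,
    read_targets,
    write_feature_tsv,
)
from rnaloc.kmer import kmer_matrix, multi_kmer_matrix
from rnaloc.metrics import EvalReport, cross_validate, make_folds
from rnaloc.model import FeatureMatrix, ModelConfig, assemble_features
from rnaloc.ppi import build_adjacency, pca_reduce
from rnaloc.synth import SynthSpec, write_corpus

logger = logging.getLogger("rnaloc")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: crc32(stage) XOR global, mod 2^31."""
    return (zlib.crc32(stage.encode()) ^ global_seed) % (2**31)


@dataclass
class RunConfig:
    """Everything one reproducible run needs, YAML round-trippable."""

    fasta: str = ""
    targets: str = ""
    ppi: str | None = None
    out_dir: str = "out"
    mode: str = "discrete"
    compartments: list[str] = field(default_factory=list)
    kmer_k: int = 5
    kmer_normalized: bool = True
    distance_k_max: int = 8
    distance_normalized: bool = True
    ppi_components: int = 500
    ppi_fit_scope: str = "whole_corpus"
    model: dict = field(default_factory=dict)  # ModelConfig overrides
    n_folds: int = 10
    n_repeats: int = 30
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def model_config(self) -> ModelConfig:
        cfg = ModelConfig(**self.model) if self.model else ModelConfig()
        cfg.seed = stage_seed(self.seed, "train")
        return cfg


def encode_features(config: RunConfig, records) -> FeatureMatrix:
    """Sequence blocks (k-mer + distance), optionally fused with PPI PCA."""
    ids = [r.id for r in records]
    kmat, _ = kmer_matrix(records, config.kmer_k, config.kmer_normalized)
    dmat, _ = distance_matrix(records, config.distance_k_max, config.distance_normalized)
    kmer_fm = FeatureMatrix(ids=ids, values=kmat)
    dist_fm = FeatureMatrix(ids=ids, values=dmat)
    ppi_fm = None
    if config.ppi:
        edges = read_ppi_edges(config.ppi)
        adj = build_adjacency(edges, ids)
        emb = pca_reduce(adj, config.ppi_components, config.ppi_fit_scope)
        ppi_fm = FeatureMatrix(ids=ids, values=emb.components)
    return assemble_features(kmer_fm, dist_fm, ppi_fm)


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute every stage and write artifacts + report under ``out_dir``.

    Writes the resolved config, the assembled feature matrix, the
    evaluation report (JSON + TSV) and a stage timing log. Rerunning
    with the same config and seed reproduces all numeric outputs.
    """
    if not config.fasta:
        raise ValueError("config field 'fasta' is required")
    if not config.targets:
        raise ValueError("config field 'targets' is required")
    if not config.compartments:
        raise ValueError("config field 'compartments' is required")
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.resolved.yaml")
    timings: dict[str, float] = {}

    def timed(stage):
        class _T:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s started", stage)
            def __exit__(self_, *exc):
                timings[stage] = time.perf_counter() - self_.t0
                logger.info("stage %s finished in %.2fs", stage, timings[stage])
        return _T()

    with timed("load"):
        records = read_fasta(config.fasta)
        targets = read_targets(config.targets, config.mode, config.compartments)
    with timed("encode"):
        features = encode_features(config, records)
        write_feature_tsv(
            features.ids, features.values,
            [f"f{i}" for i in range(features.n_features)],
            out / "features.tsv",
        )
    with timed("cross_validate"):
        ids = features.ids
        labels = targets.labels_for(ids) if config.mode == "discrete" else None
        plan = make_folds(
            ids, labels, config.n_folds, config.n_repeats,
            seed=stage_seed(config.seed, "folds"),
            stratified=config.mode == "discrete",
        )
        report = cross_validate(features, targets, config.model_config(), plan)
    with timed("report"):
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
        _write_report_tsv(report, out / "report.tsv")
        with open(out / "timings.json", "w") as fh:
            json.dump(timings, fh, indent=2)
    return report


def _write_report_tsv(report: EvalReport, path: Path) -> None:
    keys = sorted({k for d in report.per_compartment.values() for k in d})
    with open(path, "w") as fh:
        fh.write("compartment\t" + "\t".join(keys) + "\n")
        for c, d in report.per_compartment.items():
            fh.write(c + "\t" + "\t".join(f"{d.get(k, float('nan')):.6f}" for k in keys) + "\n")
        fh.write("\n# overall\n")
        for k, v in report.overall.items():
            fh.write(f"{k}\t{v:.6f}\n")


def demo_config(out_dir: str | Path, seed: int = 0, n_records: int = 400) -> RunConfig:
    """Generate a synthetic corpus on disk and a matching small RunConfig."""
    out = Path(out_dir)
    spec = SynthSpec(n_records=n_records, seed=stage_seed(seed, "synth"))
    paths = write_corpus(spec, out / "data", mode="discrete")
    return RunConfig(
        fasta=str(paths["fasta"]),
        targets=str(paths["truth"]),
        ppi=str(paths["ppi"]),
        out_dir=str(out / "run"),
        mode="discrete",
        compartments=list(spec.compartments),
        ppi_components=min(100, n_records),
        model={"epochs": 40},
        n_folds=5,
        n_repeats=1,
        seed=seed,
    )
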