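"""Pipeline orchestration: qc -> cluster -> metrics -> state (-> epitope).

Every stage is a pure function of (inputs, config, seed). A machine-readable
:class:`RunManifest` records the tool version, the effective configuration,
SHA-256 digests of all inputs, per-stage row counts and timestamps; it is
written atomically at run end (or, on failure, a partial manifest marking
the failed stage, with outputs of completed stages preserved).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .errors import PipelineError
from . import airr_io, cell_state, clonal_families, qc_filter, sequence_metrics
from .qc_filter import QCConfig
from .synthetic_data import SimulationConfig, simulate_repertoire


@dataclass
class PipelineConfig:
    """Single source of truth for a run; every CLI flag maps to a key here."""

    rearrangements: str = ""
    matrix: str = ""
    out_dir: str = "out"
    dialect: str = "airr"
    min_genes: int = 500
    min_v_length: int = 250
    threshold: float = 0.70
    linkage: str = "single"
    identity_on: str = "aa"
    state_method: str = "marker_rule"
    n_top_genes: int = 500
    seed: int = 0

    def validate(self) -> None:
        errs = []
        if self.dialect not in ("airr", "minimal"):
            errs.append(f"dialect must be airr|minimal, got {self.dialect!r}")
        if not 0 < self.threshold <= 1:
            errs.append("threshold must be in (0, 1]")
        if self.linkage not in ("single", "complete"):
            errs.append(f"linkage must be single|complete, got {self.linkage!r}")
        if self.identity_on not in ("aa", "nt"):
            errs.append(f"identity_on must be aa|nt, got {self.identity_on!r}")
        if self.state_method not in ("marker_rule", "pca_kmeans"):
            errs.append(f"state_method must be marker_rule|pca_kmeans, got {self.state_method!r}")
        if self.min_genes < 0 or self.min_v_length < 0:
            errs.append("thresholds must be non-negative")
        if not self.rearrangements:
            errs.append("rearrangements path is required")
        if not self.matrix:
            errs.append("matrix path is required")
        if errs:
            raise PipelineError("config", "; ".join(errs))


@dataclass
class RunManifest:
    version: str = __version__
    config: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    stages_completed: list = field(default_factory=list)
    failed_stage: str = ""
    seed: int = 0
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: str | Path) -> None:
        """Atomic write: temp file in the same directory, then rename."""
        path = Path(path)
        tmp = path.with_suffix(".tmp")
        tmp.write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))
        os.replace(tmp, path)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in dependency order, writing TSV/JSON outputs."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=dataclasses.asdict(config), seed=config.seed, started=time.time()
    )
    manifest_path = out / "manifest.json"
    stage = "inputs"
    try:
        for name, p in (("rearrangements", config.rearrangements), ("matrix", config.matrix)):
            if not Path(p).exists():
                raise PipelineError(stage, f"input {name} not found: {p}")
            manifest.input_digests[name] = sha256_file(p)

        stage = "qc"
        records, rejects = airr_io.read_rearrangements(config.rearrangements, config.dialect)
        profiles = airr_io.read_expression_matrix(config.matrix)
        qc_cfg = QCConfig(min_v_length=config.min_v_length, min_genes=config.min_genes)
        cells, report = qc_filter.pair_cells(records, profiles, qc_cfg)
        report.to_frame().to_csv(out / "qc_report.tsv", sep="\t", index=False)
        (out / "qc_summary.json").write_text(
            json.dumps({**report.summary(), "n_row_rejects": len(rejects)}, indent=1, sort_keys=True)
        )
        retained_records = [r for c in cells for r in (c.heavy, c.light)]
        airr_io.write_rearrangements(retained_records, out / "cells.tsv")
        manifest.stage_counts["qc"] = {
            "rows_in": len(records),
            "row_rejects": len(rejects),
            "cells_in": len(report.outcomes),
            "cells_retained": len(cells),
        }
        manifest.stages_completed.append("qc")

        stage = "cluster"
        families = clonal_families.build_clonal_families(
            cells, threshold=config.threshold, linkage=config.linkage, on=config.identity_on
        )
        families = clonal_families.annotate_convergence(families)
        clonal_families.membership_frame(families).to_csv(out / "cf_membership.tsv", sep="\t", index=False)
        clonal_families.summary_frame(families).to_csv(out / "cf_summary.tsv", sep="\t", index=False)
        n_convergent = sum(f.is_convergent for f in families)
        (out / "cf_stats.json").write_text(
            json.dumps(
                {
                    "n_cells": sum(f.size for f in families),
                    "n_families": len(families),
                    "n_convergent": n_convergent,
                    "threshold": config.threshold,
                    "linkage": config.linkage,
                },
                indent=1,
                sort_keys=True,
            )
        )
        manifest.stage_counts["cluster"] = {
            "cells_in": len(cells),
            "n_families": len(families),
            "n_convergent": n_convergent,
        }
        manifest.stages_completed.append("cluster")

        stage = "metrics"
        if len(cells) >= 2:
            for chain in ("VH", "VL"):
                dm = sequence_metrics.distance_matrix(cells, chain=chain)
                dm.to_frame().to_csv(out / f"edit_distance_{chain}.tsv", sep="\t")
        sequence_metrics.shm_table(cells).to_csv(out / "shm.tsv", sep="\t", index=False)
        for fam in families:
            if fam.is_convergent:
                pfm = sequence_metrics.logo_pfm(
                    [clonal_families.cell_cdr3(m) for m in fam.members]
                )
                pfm.to_frame().to_csv(out / f"logo_pfm_{fam.cf_id}.tsv", sep="\t")
        manifest.stage_counts["metrics"] = {"cells_in": len(cells)}
        manifest.stages_completed.append("metrics")

        stage = "state"
        calls = cell_state.classify_state(
            profiles,
            method=config.state_method,
            seed=config.seed,
            n_top_genes=config.n_top_genes,
        )
        cell_state.state_frame(calls).to_csv(out / "cell_state.tsv", sep="\t", index=False)
        manifest.stage_counts["state"] = {
            "cells_in": len(profiles),
            "n_plasmablast": sum(c.state == cell_state.PLASMABLAST for c in calls),
        }
        manifest.stages_completed.append("state")
    except PipelineError:
        manifest.failed_stage = stage
        manifest.finished = time.time()
        manifest.write(manifest_path)
        raise
    except Exception as exc:
        manifest.failed_stage = stage
        manifest.finished = time.time()
        manifest.write(manifest_path)
        raise PipelineError(stage, str(exc)) from exc
    manifest.finished = time.time()
    manifest.write(manifest_path)
    return manifest


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict:
    """Run the simulator and write rearrangements, counts and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records, profiles, truth = simulate_repertoire(config)
    airr_io.write_rearrangements(records, out / "rearrangements.tsv")
    airr_io.write_expression_matrix(profiles, out / "counts.tsv")
    truth.to_json(out / "ground_truth.json")
    return {
        "rearrangements": str(out / "rearrangements.tsv"),
        "matrix": str(out / "counts.tsv"),
        "ground_truth": str(out / "ground_truth.json"),
        "n_records": len(records),
        "n_cells": len(profiles),
    }
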