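"""End-to-end orchestration: expression → gene scores → h-values → geometry →
sub-networks → robustness, with a manifest for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import geometry as geom
from . import robustness as rob
from . import stats as st
from . import subnetworks as sn
from .model import MetabolicModel, read_model
from .stats import ReactionHValues

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "read_expression", "read_phenotype"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    model_path: str
    expression_path: str
    phenotype_path: str
    outdir: str
    model_format: str = "table"
    mode: str = "correlation"  # or "two_group"
    case_label: str = "deceased"
    direction: str = "positive"
    q: float = 0.05
    h_min: float | None = None  # default depends on mode
    theta_max: float = sn.THETA_MAX
    tol_angle: float = geom.TOL_ANGLE
    tol_blocked: float = geom.TOL_BLOCKED
    min_seed: int = sn.MIN_SEED
    top_n: int = 100
    k_hub: int = 5
    seed: int = 0
    ppi_path: str | None = None
    id_map_path: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("correlation", "two_group"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.q < 1:
            raise ValueError("q must be in (0, 1)")
        if self.h_min is None:
            self.h_min = sn.H_MIN if self.mode == "correlation" else sn.H_MIN_TWO_GROUP
        if not 0 < self.h_min < 1:
            raise ValueError("h_min must be in (0, 1)")
        if not 0 < self.theta_max <= 90:
            raise ValueError("theta_max must be in (0, 90]")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes × samples TSV; first column gene id, header = sample ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_phenotype(path: str | Path) -> pd.Series:
    """Two-column TSV (sample id, value-or-group)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def _sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write reports under ``config.outdir``.

    Outputs: gene_scores.tsv, reaction_h.tsv, subnetworks.json,
    subnetworks.txt, robustness.tsv, robustness.json and manifest.json.
    Deterministic given config and inputs; the manifest records config and
    input hashes.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc

    model: MetabolicModel = stage(
        "read_model", read_model, config.model_path, config.model_format
    )
    expr = stage("read_expression", read_expression, config.expression_path)
    phen = stage("read_phenotype", read_phenotype, config.phenotype_path)

    if config.mode == "correlation":
        scores = stage("score", st.spearman_scores, expr, phen.astype(float))
    else:
        scores = stage(
            "score", st.ttest_scores, expr, phen.astype(str), config.case_label
        )
    scores.to_csv(out / "gene_scores.tsv", sep="\t")

    selected = stage("fdr_select", st.fdr_select, scores, config.q, config.direction)
    (out / "selected_genes.txt").write_text(
        "\n".join(sorted(selected)) + "\n", encoding="utf-8"
    )

    h: ReactionHValues = stage(
        "h_values", st.reaction_h_values, scores, model, config.direction
    )
    h.table.to_csv(out / "reaction_h.tsv", sep="\t")

    geometry = stage(
        "geometry", geom.compute_geometry, model, config.tol_blocked
    )
    subnets = stage(
        "subnetworks",
        sn.detect_subnetworks,
        geometry,
        h,
        model,
        config.h_min,
        config.theta_max,
        config.min_seed,
        config.tol_angle,
    )[: config.top_n]
    (out / "subnetworks.json").write_text(
        sn.subnetworks_to_json(subnets), encoding="utf-8"
    )
    sn.write_subnetwork_report(subnets, model, out / "subnetworks.txt")

    reports = [stage("robustness", rob.analyze_subnetwork, s, model) for s in subnets]
    rob.robustness_table(reports, out / "robustness.tsv")
    (out / "robustness.json").write_text(
        rob.reports_to_json(reports), encoding="utf-8"
    )

    manifest = {
        "config": json.loads(config.to_json()),
        "config_hash": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "inputs": {
            "model": _sha256_file(config.model_path),
            "expression": _sha256_file(config.expression_path),
            "phenotype": _sha256_file(config.phenotype_path),
        },
        "n_genes_selected": len(selected),
        "n_subnetworks": len(subnets),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    logger.info(
        "pipeline done: %d genes selected, %d sub-networks", len(selected), len(subnets)
    )
    return manifest
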