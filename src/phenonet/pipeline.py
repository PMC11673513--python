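"""End-to-end orchestration: simulate -> preprocess -> ANOVA -> network.

A :class:`RunConfig` carries every analysis constant (RSD cutoff, the two
alpha thresholds, reference cell, top-k, sums-of-squares type, seed) plus
either a simulation configuration or paths to an existing feature table and
cohort CSV.  :func:`run_all` executes the stages in order and returns a
:class:`RunResult` bundling the machine-readable :class:`RunReport` (pure
JSON-serializable counts, tables and provenance) with the in-memory stage
artifacts; :func:`write_report` persists everything.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .anova import (
    DEFAULT_ALPHA,
    SignificanceSets,
    direction_table,
    group_summary,
    run_anova,
    run_posthoc,
    select_significant,
    subgroup_correlations,
)
from .network import (
    DEFAULT_TOP_K,
    assign_degrees_and_weights,
    build_network,
    edge_list,
    eigenvector_centrality,
    rank_top_k,
    ranking_table,
    write_graphml,
)
from .preprocess import DEFAULT_RSD_THRESHOLD, preprocess_pipeline
from .synth import SimConfig, add_qc_samples, generate_cohort
from .tables import (
    read_cohort,
    read_feature_table,
    write_cohort,
    write_feature_table,
    write_truth_labels,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    sim: SimConfig | None = None
    feature_table_path: str | None = None
    cohort_path: str | None = None
    rsd_threshold: float = DEFAULT_RSD_THRESHOLD
    alpha_anova: float = DEFAULT_ALPHA
    alpha_network: float = DEFAULT_ALPHA
    reference_cell: str = "ObeseLow"
    top_k: int = DEFAULT_TOP_K
    ss_type: str = "I"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rsd_threshold", "alpha_anova", "alpha_network"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.sim is None and (
            self.feature_table_path is None or self.cohort_path is None
        ):
            raise ValueError(
                "provide either a simulation config or input table paths"
            )

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("sim", None)
        sim = None
        if sim_raw is not None:
            if "n_per_cell" in sim_raw:
                sim_raw["n_per_cell"] = tuple(sim_raw["n_per_cell"])
            sim = SimConfig(**sim_raw)
        return cls(sim=sim, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        if raw["sim"] is not None:
            raw["sim"]["n_per_cell"] = list(raw["sim"]["n_per_cell"])
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class RunReport:
    """JSON-serializable summary of one run (counts, tables, provenance)."""

    counts: dict
    venn: dict
    subgroup_correlations: list
    group_summary: list
    top_k: list
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunReport":
        return cls(**raw)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        return cls.from_dict(json.loads(text))


@dataclass
class RunResult:
    """Report plus the in-memory artifacts of every stage."""

    report: RunReport
    config: RunConfig
    meta: pd.DataFrame
    table: "object"
    processed: "object"
    rsd_report: "object"
    records: pd.DataFrame
    sets: SignificanceSets
    posthoc: dict
    direction: pd.DataFrame
    subgroup: pd.DataFrame
    summary: pd.DataFrame
    network: "object"
    ranking: "object"
    top: list = field(default_factory=list)


def _load_inputs(config: RunConfig):
    if config.sim is not None:
        sim = config.sim.replace(seed=config.seed)
        meta, table = generate_cohort(sim)
        table = add_qc_samples(table, sim)
        return meta, table
    table = read_feature_table(config.feature_table_path)
    meta = read_cohort(config.cohort_path)
    return meta, table


def run_all(config: RunConfig) -> RunResult:
    """Execute every stage in order; deterministic for a fixed config."""
    logger.info("stage input: %s", "simulate" if config.sim else "load")
    meta, table = _load_inputs(config)
    logger.info("input table: %d samples x %d features", *table.abundances.shape)

    processed, rsd_report = preprocess_pipeline(table, config.rsd_threshold)
    records = run_anova(processed, meta, ss_type=config.ss_type)
    sets = select_significant(records, config.alpha_anova)
    logger.info(
        "selection: |BMI|=%d |IPAQ|=%d |interaction|=%d union=%d",
        len(sets.set_bmi), len(sets.set_ipaq),
        len(sets.set_interaction), len(sets.union),
    )
    posthoc = run_posthoc(
        processed, meta, sorted(sets.union), config.reference_cell,
        config.alpha_anova,
    )
    direction = direction_table(records, posthoc, sets, config.alpha_anova)
    subgroup = subgroup_correlations(meta)
    summary = group_summary(meta)

    net = build_network(
        processed, sorted(sets.union), meta, alpha=config.alpha_network
    )
    assign_degrees_and_weights(net)
    ranking = eigenvector_centrality(net)
    top = rank_top_k(ranking, config.top_k)
    logger.info(
        "network: %d nodes, %d edges, eigenvalue %.4f",
        net.n_nodes, net.n_edges, ranking.eigenvalue,
    )

    counts = {
        "features_in": rsd_report.n_input,
        "features_removed_rsd": rsd_report.n_removed,
        "features_retained": rsd_report.n_retained,
        "n_study_samples": int(table.study_mask().sum()),
        "n_qc_samples": int(table.qc_mask().sum()),
        "set_bmi": len(sets.set_bmi),
        "set_ipaq": len(sets.set_ipaq),
        "set_interaction": len(sets.set_interaction),
        "union": len(sets.union),
        "network_nodes": net.n_nodes,
        "network_edges": net.n_edges,
    }
    report = RunReport(
        counts=counts,
        venn=sets.region_counts(),
        subgroup_correlations=subgroup.reset_index().to_dict(orient="records"),
        group_summary=summary.to_dict(orient="records"),
        top_k=[
            {"rank": i + 1, "node": node, "score": float(ranking.scores[node])}
            for i, node in enumerate(top)
        ],
        provenance={
            "phenonet_version": __version__,
            "seed": config.seed,
            "rsd_threshold": config.rsd_threshold,
            "alpha_anova": config.alpha_anova,
            "alpha_network": config.alpha_network,
            "reference_cell": config.reference_cell,
            "top_k": config.top_k,
            "ss_type": config.ss_type,
            "simulated": config.sim is not None,
            "eigenvalue": float(ranking.eigenvalue),
        },
    )
    return RunResult(
        report=report, config=config, meta=meta, table=table,
        processed=processed, rsd_report=rsd_report, records=records,
        sets=sets, posthoc=posthoc, direction=direction, subgroup=subgroup,
        summary=summary, network=net, ranking=ranking, top=top,
    )


def write_report(result: RunResult, out_dir: str | Path) -> Path:
    """Write report.json plus all stage artifacts; returns the report path."""
    out = Path(out_dir)
    if not out.exists():
        logger.info("creating output directory %s", out)
        out.mkdir(parents=True, exist_ok=True)

    report_path = out / "report.json"
    report_path.write_text(result.report.to_json() + "\n")

    write_cohort(result.meta, out / "cohort.csv")
    write_feature_table(result.table, out / "feature_table.csv")
    if result.table.truth_labels is not None:
        write_truth_labels(result.table, out / "truth_labels.csv")
    result.rsd_report.to_csv(out / "rsd_report.csv")
    proc = result.processed.data.copy()
    proc.index.name = "sample_id"
    proc.to_csv(out / "processed.csv")
    result.records.to_csv(out / "anova_records.csv")
    result.direction.to_csv(out / "direction_table.csv", index=False)
    result.subgroup.to_csv(out / "subgroup_correlations.csv")
    result.summary.to_csv(out / "group_summary.csv", index=False)
    edge_list(result.network).to_csv(out / "edges.csv", index=False)
    write_graphml(result.network, out / "network.graphml", result.ranking)
    ranking_table(
        result.ranking, result.config.top_k, result.records, result.sets
    ).to_csv(out / "ranking.csv", index=False)
    return report_path
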