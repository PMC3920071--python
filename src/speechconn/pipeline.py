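"""Configuration-driven orchestration of the analysis stages.

A run is described by a :class:`RunConfig` (usually loaded from YAML): where
the cohort comes from (a manifest on disk, or simulation parameters), which
analyses to execute, the permutation settings, and the output directory.
Every report carries the master seed and a hash of the configuration, and a
re-run with an identical configuration reproduces every output byte for
byte (no timestamps or machine state enter the outputs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import Cohort
from .edgewise import add_fdr, ranksum_edges, spearman_edges, write_edge_table
from .errors import ValidationError
from .graphmetrics import metric_group_tests, subject_metrics
from .nbs import (
    PermutationPlan,
    components_report,
    export_graphml,
    nbs_correlation,
    nbs_group,
    sign_bias_test,
    write_report,
)
from .parcellation import Parcellation
from .simulate import EffectSpec, NoiseSpec, simulate_cohort

log = logging.getLogger("speechconn")

ANALYSES = ("edgewise", "nbs_group", "nbs_correlation", "sign_bias", "graph")


@dataclass
class RunConfig:
    output_dir: str
    seed: int = 0
    cohort_manifest: str | None = None
    simulate: dict | None = None
    parcellation: str | None = None
    layout: str = "intra_left"
    analyses: tuple[str, ...] = ANALYSES
    n_iterations: int = 1000
    edge_p_threshold_group: float = 0.01
    edge_p_threshold_correlation: float = 0.05
    sign_bias_scope: str = "significant_edges"
    fdr_q: float = 0.05

    def __post_init__(self) -> None:
        if self.cohort_manifest is None and self.simulate is None:
            raise ValidationError("config needs either cohort_manifest or simulate settings")
        unknown = set(self.analyses) - set(ANALYSES)
        if unknown:
            raise ValidationError(f"unknown analyses {sorted(unknown)}; expected from {ANALYSES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        if "analyses" in data:
            data["analyses"] = tuple(data["analyses"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValidationError(f"{path}: {exc}") from None

    def to_dict(self) -> dict:
        return {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "cohort_manifest": self.cohort_manifest,
            "simulate": self.simulate,
            "parcellation": self.parcellation,
            "layout": self.layout,
            "analyses": list(self.analyses),
            "n_iterations": self.n_iterations,
            "edge_p_threshold_group": self.edge_p_threshold_group,
            "edge_p_threshold_correlation": self.edge_p_threshold_correlation,
            "sign_bias_scope": self.sign_bias_scope,
            "fdr_q": self.fdr_q,
        }

    def content_hash(self) -> str:
        """Hash of everything that determines the outputs (not the out dir)."""
        payload = self.to_dict()
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _build_cohort(config: RunConfig) -> Cohort:
    if config.cohort_manifest is not None:
        return Cohort.from_manifest(config.cohort_manifest)
    sim = dict(config.simulate or {})
    parcellation = (
        Parcellation.from_yaml(config.parcellation) if config.parcellation else None
    )
    effect = EffectSpec(
        target_edges=sim.get("target_edges"),
        effect_multiplier=sim.get("effect_multiplier", 1.0),
        severity_edges=sim.get("severity_edges"),
        severity_slope=sim.get("severity_slope", 0.0),
    )
    noise = NoiseSpec(
        sigma=sim.get("sigma", 0.2),
        subject_sigma=sim.get("subject_sigma", 0.0),
        strength=sim.get("strength", 1.0),
        scale=sim.get("scale", 3.0),
    )
    layouts = tuple(sim.get("layouts", (config.layout,)))
    return simulate_cohort(
        parcellation=parcellation,
        n_case=sim.get("n_case", 20),
        n_control=sim.get("n_control", 17),
        effect=effect,
        noise=noise,
        seed=config.seed,
        layouts=layouts,
        effect_layout=sim.get("effect_layout", config.layout),
    )


def run(config: RunConfig) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the summary report (also written as report.json).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"seed": config.seed, "config_hash": config.content_hash()}
    summary: dict = {"config": config.to_dict(), **stamp, "outputs": {}}

    t0 = time.perf_counter()
    cohort = _build_cohort(config)
    log.info("cohort ready: %d subjects (%.2fs)", cohort.n_subjects, time.perf_counter() - t0)
    layout = config.layout
    has_severity = any(s.severity is not None for s in cohort.subjects)

    if "edgewise" in config.analyses:
        t = time.perf_counter()
        table = add_fdr(ranksum_edges(cohort, layout), q=config.fdr_q)
        path = out / f"edgewise_ranksum_{layout}.tsv"
        write_edge_table(table, path)
        summary["outputs"]["edgewise_ranksum"] = path.name
        if has_severity:
            table = add_fdr(spearman_edges(cohort, layout), q=config.fdr_q)
            path = out / f"edgewise_spearman_{layout}.tsv"
            write_edge_table(table, path)
            summary["outputs"]["edgewise_spearman"] = path.name
        log.info("edgewise done (%.2fs)", time.perf_counter() - t)

    if "nbs_group" in config.analyses:
        t = time.perf_counter()
        plan = PermutationPlan(
            n_iterations=config.n_iterations,
            edge_p_threshold=config.edge_p_threshold_group,
            tail="case_lt_control",
            seed=config.seed,
        )
        comps = nbs_group(cohort, layout, plan)
        report = components_report(comps, plan, extra=stamp)
        write_report(report, out / "nbs_group.json")
        summary["outputs"]["nbs_group"] = "nbs_group.json"
        for k, comp in enumerate(c for c in comps if (c.corrected_p or 1.0) < 0.05):
            export_graphml(comp, out / f"nbs_group_component{k}.graphml")
        log.info("nbs_group done (%.2fs)", time.perf_counter() - t)

    if "nbs_correlation" in config.analyses and has_severity:
        t = time.perf_counter()
        plan = PermutationPlan(
            n_iterations=config.n_iterations,
            edge_p_threshold=config.edge_p_threshold_correlation,
            tail="negative_correlation",
            seed=config.seed,
        )
        comps = nbs_correlation(cohort, layout, plan)
        write_report(components_report(comps, plan, extra=stamp), out / "nbs_correlation.json")
        summary["outputs"]["nbs_correlation"] = "nbs_correlation.json"
        for k, comp in enumerate(c for c in comps if (c.corrected_p or 1.0) < 0.05):
            export_graphml(comp, out / f"nbs_correlation_component{k}.graphml")
        log.info("nbs_correlation done (%.2fs)", time.perf_counter() - t)

    if "sign_bias" in config.analyses:
        t = time.perf_counter()
        plan = PermutationPlan(
            n_iterations=config.n_iterations, tail="case_lt_control", seed=config.seed
        )
        result = sign_bias_test(cohort, layout, plan, count_scope=config.sign_bias_scope)
        write_report({**result.to_dict(), **stamp}, out / "sign_bias.json")
        summary["outputs"]["sign_bias"] = "sign_bias.json"
        log.info("sign_bias done (%.2fs)", time.perf_counter() - t)

    if "graph" in config.analyses:
        t = time.perf_counter()
        metrics = subject_metrics(cohort, layout)
        metrics.to_csv(out / "graph_metrics_subjects.tsv", sep="\t", index=False,
                       float_format="%.12g")
        tests = metric_group_tests(cohort, layout)
        tests.to_csv(out / "graph_metrics_tests.tsv", sep="\t", index=False,
                     float_format="%.12g")
        summary["outputs"]["graph_metrics"] = "graph_metrics_subjects.tsv"
        summary["outputs"]["graph_tests"] = "graph_metrics_tests.tsv"
        log.info("graph done (%.2fs)", time.perf_counter() - t)

    write_report(summary, out / "report.json")
    return summary
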