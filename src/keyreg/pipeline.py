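"""End-to-end orchestration of the four-stage pipeline.

``run_pipeline`` wires the stages together —

    differential expression  ->  network inference  ->  enrichment  ->  ranking

— persisting each stage's table as TSV plus a ``run_manifest.json`` that
echoes the fully resolved configuration, so a run is reproducible from
its manifest alone.  A user-supplied edge list replaces the network
stage.  All randomness flows from the single ``seed`` in the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .diffexpr import (
    DEResult,
    design_matrix,
    likelihood_ratio_test,
    moderated_t_test,
    nb_wald_test,
)
from .enrichment import (
    EnrichmentResult,
    fet_enrich,
    gsea_empirical_p,
    make_ranking_metric,
)
from .io import (
    ExpressionData,
    attach_metadata,
    load_regulators,
    read_expression,
    read_metadata,
    read_network_tsv,
    write_network_tsv,
)
from .netinfer import RegulatorNetwork, hub_metrics, infer_network
from .ranking import RegulatorRanking, rank_regulators

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "run_pipeline_files", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and a remediation hint."""

    def __init__(self, stage: str, message: str, hint: str = ""):
        self.stage = stage
        self.hint = hint
        super().__init__(f"[{stage}] {message}" + (f" (hint: {hint})" if hint else ""))


@dataclass
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Loadable from YAML (JSON is valid YAML) via :meth:`from_file`; CLI
    flags override file values.  Paths may be None when the pipeline is
    driven from in-memory objects.
    """

    expr: str | None = None
    meta: str | None = None
    regulators: str | None = None       # None -> bundled default list
    user_network: str | None = None     # skip inference when given
    out_dir: str = "keyreg_out"
    kind: str = "continuous"            # counts | continuous
    log2_transform: bool = False        # apply log2(x+1) to counts before COEN/GRN
    de_method: str = "auto"             # auto | wald | moderated_t | lrt
    design: list[str] = field(default_factory=lambda: ["group"])
    reduced: list[str] = field(default_factory=list)
    network_method: str = "coen"        # coen | grn
    edge_fraction: float = 0.05
    soft_power: int | None = None
    powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_target: float = 0.85
    n_trees: int = 1000
    grn_quality_threshold: float = 0.0
    enrich_method: str = "gsea"         # fet | gsea
    n_perm: int = 1000
    de_fdr: float = 0.05
    min_set_size: int = 3
    seed: int = 0
    n_jobs: int = 1

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _run_de(expr: ExpressionData, cfg: PipelineConfig) -> DEResult:
    method = cfg.de_method
    n_groups = expr.groups.nunique()
    if method == "auto":
        if n_groups > 2:
            method = "lrt"
        else:
            method = "wald" if expr.kind == "counts" else "moderated_t"
    if method == "wald":
        return nb_wald_test(expr)
    if method == "moderated_t":
        return moderated_t_test(expr)
    if method == "lrt":
        full = design_matrix(expr.annotations, cfg.design)
        reduced = design_matrix(expr.annotations, cfg.reduced)
        return likelihood_ratio_test(expr, full, reduced)
    raise ValueError(f"unknown DE method: {method!r}")


def _run_network(
    expr: ExpressionData, regulators: list[str], cfg: PipelineConfig
) -> RegulatorNetwork:
    if cfg.user_network is not None:
        edges = read_network_tsv(cfg.user_network)
        return RegulatorNetwork(edges=edges, regulators=sorted(set(edges["regulator"])))
    net_expr = expr.log2_cpm_like() if (expr.kind == "counts" or cfg.log2_transform) else expr
    return infer_network(
        net_expr,
        regulators,
        method=cfg.network_method,
        edge_fraction=cfg.edge_fraction,
        beta=cfg.soft_power,
        powers=cfg.powers,
        r2_target=cfg.r2_target,
        n_trees=cfg.n_trees,
        grn_quality_threshold=cfg.grn_quality_threshold,
        seed=cfg.seed,
        n_jobs=cfg.n_jobs,
    )


def _run_enrichment(
    net: RegulatorNetwork, de: DEResult, cfg: PipelineConfig
) -> EnrichmentResult:
    if cfg.enrich_method == "fet":
        de_genes = de.significant_genes(cfg.de_fdr)
        return fet_enrich(net, de_genes, min_set_size=cfg.min_set_size)
    if cfg.enrich_method == "gsea":
        network_nodes = set(net.nodes)
        metric = make_ranking_metric(de, genes=network_nodes)
        return gsea_empirical_p(
            metric,
            net.target_sets(),
            n_perm=cfg.n_perm,
            seed=cfg.seed,
            min_set_size=cfg.min_set_size,
        )
    raise ValueError(f"unknown enrichment method: {cfg.enrich_method!r}")


def _rank(de: DEResult, enr: EnrichmentResult, regulators: list[str]) -> RegulatorRanking:
    regs = [r for r in regulators if r in set(enr.regulator_ids)]
    p_d = de.table["p_value"].reindex(regs)
    p_e = enr.table["p_value"].reindex(regs)
    extra = enr.table[["es", "n_targets", "overlap"]].reindex(regs)
    extra = extra.join(de.table[["log_fc"]].reindex(regs))
    return rank_regulators(p_d, p_e, extra=extra)


def regulator_targets_table(
    net: RegulatorNetwork, de: DEResult, de_fdr: float = 0.05
) -> pd.DataFrame:
    """Tabular regulator/target export (the plotting-free regulon view)."""
    de_set = set(de.significant_genes(de_fdr))
    out = net.edges.copy()
    out["target_in_de_set"] = out["target"].isin(de_set)
    return out


def run_pipeline(
    expr: ExpressionData,
    regulators: list[str],
    cfg: PipelineConfig,
    out_dir: str | Path | None = None,
) -> RegulatorRanking:
    """Run DE -> network -> enrichment -> ranking on in-memory inputs.

    When ``out_dir`` is given all intermediate tables and the manifest
    are persisted there; on a stage failure, outputs written so far are
    renamed with a ``.partial`` suffix and a :class:`PipelineError` names
    the failed stage.
    """
    out = Path(out_dir) if out_dir is not None else None
    written: list[Path] = []
    timings: dict[str, float] = {}

    def _persist(name: str, writer) -> None:
        if out is None:
            return
        out.mkdir(parents=True, exist_ok=True)
        path = out / name
        writer(path)
        written.append(path)

    def _stage(name: str, fn, hint: str):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            for p in written:
                p.rename(p.with_suffix(p.suffix + ".partial"))
            raise PipelineError(name, str(exc), hint) from exc
        timings[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.2fs", name, timings[name])
        return result

    de = _stage(
        "differential_expression",
        lambda: _run_de(expr, cfg),
        "check data kind, group labels and design columns",
    )
    _persist("de_results.tsv", de.write_tsv)

    net = _stage(
        "network_inference",
        lambda: _run_network(expr, regulators, cfg),
        "check the regulator list overlaps the expression genes",
    )
    _persist("network_edges.tsv", lambda p: write_network_tsv(net.edges, p))

    enr = _stage(
        "enrichment",
        lambda: _run_enrichment(net, de, cfg),
        "check de_fdr / min_set_size against the network's regulon sizes",
    )
    _persist("enrichment.tsv", enr.write_tsv)

    ranking = _stage(
        "ranking",
        lambda: _rank(de, enr, regulators),
        "DE and enrichment tables must cover the same regulators",
    )
    _persist("ranking.tsv", ranking.write_tsv)
    _persist(
        "regulator_targets.tsv",
        lambda p: regulator_targets_table(net, de, cfg.de_fdr).to_csv(
            p, sep="\t", index=False, float_format="%.6g"
        ),
    )
    _persist(
        "hub_metrics.tsv",
        lambda p: hub_metrics(net).to_csv(p, sep="\t", float_format="%.6g"),
    )

    if out is not None:
        manifest = {
            "package": "keyreg",
            "version": __version__,
            "config": cfg.to_dict(),
            "n_genes": expr.n_genes,
            "n_samples": expr.n_samples,
            "n_regulators": len(regulators),
            "n_edges": net.n_edges,
            "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return ranking


def run_pipeline_files(cfg: PipelineConfig) -> RegulatorRanking:
    """File-driven entry point (the ``keyreg run`` command)."""
    if cfg.expr is None or cfg.meta is None:
        raise PipelineError("input", "config must set 'expr' and 'meta' paths",
                            "see PipelineConfig")
    try:
        expr = read_expression(cfg.expr, kind=cfg.kind)
        expr = attach_metadata(expr, read_metadata(cfg.meta))
    except Exception as exc:
        raise PipelineError("input", str(exc), "validate the expression/metadata TSVs") from exc
    regulators = load_regulators(cfg.regulators)
    return run_pipeline(expr, regulators, cfg, out_dir=cfg.out_dir)
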