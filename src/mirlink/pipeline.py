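"""End-to-end orchestration: preprocess -> DE / enrichment -> link -> network.

Stages run in the integration order: both matrices are preprocessed, the
miRNA matrix goes through the moderated t-test while the mRNA matrix goes
through GSEA with leading-edge refinement, significant sets are merged into
modules, DE miRNAs are linked to modules by the anti-correlation rule, and
each module's interactome is built and overlaid with its linked miRNAs.
Every stage's outputs are written as plain-text files so any single stage
can be re-run from the intermediates; a run log records seeds, thresholds
and counts at each stage.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import yaml

from . import io as mio
from .containers import ExpressionMatrix, FeatureKind, GroupDesign
from .diffexp import ModeratedTTest
from .gsea import GeneSetEnrichment
from .integrate import bipartite_summary, link_mirnas_to_modules
from .network import (
    build_interactome,
    most_targeted_genes,
    overlay_mirnas,
    top_hubs,
    write_graphml,
    write_node_edge_tables,
)
from .preprocess import collapse_probes, filter_detected, quantile_normalize

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs, thresholds and options of a full integration run."""

    mrna_path: str = ""
    mirna_path: str = ""
    design_path: str = ""
    gene_sets_path: str = ""
    targets_path: str = ""
    interactions_path: str = ""
    outdir: str = "mirlink_out"
    collapse_map_path: Optional[str] = None
    merge_spec_path: Optional[str] = None
    drop_samples: Tuple[str, ...] = ()
    n_perm: int = 2000
    q_de: float = 0.05
    q_enrich: float = 0.05
    weight: float = 1.0
    metric: str = "signal_to_noise"
    min_set_size: int = 5
    max_set_size: int = 500
    prior_df: float = 10.0
    window_size: int = 101
    mirna_min_detect_fraction: float = 1.0
    auto_merge: bool = False
    jaccard_threshold: float = 0.5
    anchors: Tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("q_de", "q_enrich"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0,1), got {v}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("drop_samples", "anchors"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)


def _safe_name(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._+-]+", "_", name)


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run every stage and write the results bundle under ``cfg.outdir``.

    Returns a dict with the in-memory results (DE records, enrichment,
    modules, links, networks) and the paths written.  Any stage error is
    re-raised as :class:`StageError` naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = [
        "mirlink pipeline run",
        f"seed: {cfg.seed}",
        f"n_perm: {cfg.n_perm}",
        f"q_de: {cfg.q_de}  q_enrich: {cfg.q_enrich}",
        f"metric: {cfg.metric}  weight: {cfg.weight}",
        f"set size: [{cfg.min_set_size}, {cfg.max_set_size}]",
        f"moderated t: prior_df={cfg.prior_df} window={cfg.window_size}",
    ]
    paths: Dict[str, str] = {}

    # ---- load ----------------------------------------------------------
    stage = "load"
    try:
        mrna = mio.read_expression_tsv(cfg.mrna_path, FeatureKind.GENE)
        mirna = mio.read_expression_tsv(cfg.mirna_path, FeatureKind.MIRNA)
        design = mio.read_design(cfg.design_path)
        sets = mio.read_gmt(cfg.gene_sets_path)
        cmap = (
            mio.read_collapse_map(cfg.collapse_map_path)
            if cfg.collapse_map_path
            else None
        )
        merge_spec = None
        if cfg.merge_spec_path:
            with open(cfg.merge_spec_path) as fh:
                merge_spec = yaml.safe_load(fh)
            if merge_spec is not None and not isinstance(merge_spec, dict):
                raise ValueError("merge spec must map set names to module names")
    except Exception as e:
        raise StageError(stage, e) from e
    log_lines += [
        f"[load] mrna: {mrna.n_features} features x {mrna.n_samples} samples",
        f"[load] mirna: {mirna.n_features} features x {mirna.n_samples} samples",
        f"[load] gene sets: {len(sets)}",
    ]

    # ---- preprocess ----------------------------------------------------
    stage = "preprocess"
    try:
        if cfg.drop_samples:
            mrna = mrna.drop_samples(list(cfg.drop_samples))
            log_lines.append(f"[preprocess] dropped samples: {list(cfg.drop_samples)}")
        if mirna.detected is not None:
            before = mirna.n_features
            mirna = filter_detected(mirna, cfg.mirna_min_detect_fraction)
            log_lines.append(
                f"[preprocess] miRNA detection filter: {before} -> {mirna.n_features}"
            )
        if cmap is not None:
            mrna = collapse_probes(mrna, cmap)
            log_lines.append(f"[preprocess] collapsed to {mrna.n_features} genes")
        mrna = quantile_normalize(mrna)
        mirna = quantile_normalize(mirna)
        design_mrna = design.restrict(mrna.sample_ids)
        design_mirna = design.restrict(mirna.sample_ids)
    except Exception as e:
        raise StageError(stage, e) from e

    # ---- miRNA differential expression ---------------------------------
    stage = "diffexp"
    try:
        de_res = ModeratedTTest(
            mirna, design_mirna, prior_df=cfg.prior_df, window_size=cfg.window_size
        ).fit()
        de_sig = de_res.significant(cfg.q_de)
        paths["de_mirna"] = str(outdir / "de_mirna.tsv")
        mio.write_de_table(de_res.records, paths["de_mirna"])
    except Exception as e:
        raise StageError(stage, e) from e
    n_up = sum(1 for r in de_sig if r.direction == "up")
    log_lines.append(
        f"[diffexp] {len(de_sig)} miRNAs at Q<={cfg.q_de} "
        f"({n_up} up, {len(de_sig) - n_up} down)"
    )

    # ---- mRNA enrichment ------------------------------------------------
    stage = "gsea"
    try:
        enr = GeneSetEnrichment(
            mrna,
            design_mrna,
            sets,
            metric=cfg.metric,
            weight=cfg.weight,
            n_perm=cfg.n_perm,
            min_size=cfg.min_set_size,
            max_size=cfg.max_set_size,
            seed=cfg.seed,
        ).fit()
        paths["enrichment"] = str(outdir / "enrichment.tsv")
        mio.write_enrichment_table(enr.results, paths["enrichment"])
        modules = enr.merge_modules(
            merge_spec=merge_spec,
            q_threshold=cfg.q_enrich,
            auto=cfg.auto_merge,
            jaccard_threshold=cfg.jaccard_threshold,
        )
        paths["modules"] = str(outdir / "modules.json")
        mio.write_modules_json(modules, paths["modules"])
    except Exception as e:
        raise StageError(stage, e) from e
    log_lines.append(
        f"[gsea] {len(enr.significant(cfg.q_enrich))} sets at Q<={cfg.q_enrich}; "
        f"{len(modules)} modules"
    )

    # ---- integrate -------------------------------------------------------
    stage = "integrate"
    try:
        if not cfg.targets_path:
            raise ValueError("no miRNA target-map path configured")
        tmap = mio.read_target_map(cfg.targets_path)
        linkage = link_mirnas_to_modules(de_sig, tmap, modules)
        paths["links"] = str(outdir / "links.tsv")
        mio.write_links_tsv(linkage.links, paths["links"])
        paths["unlinked"] = str(outdir / "unlinked_mirnas.txt")
        with open(paths["unlinked"], "w") as fh:
            for m in linkage.unlinked_mirnas:
                fh.write(m + "\n")
        paths["bipartite"] = str(outdir / "bipartite.json")
        import json as _json

        with open(paths["bipartite"], "w") as fh:
            _json.dump(bipartite_summary(linkage.links), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception as e:
        raise StageError(stage, e) from e
    log_lines.append(
        f"[integrate] {len(linkage.links)} miRNA-module links; "
        f"{len(linkage.unlinked_mirnas)} DE miRNAs unlinked"
    )

    # ---- network ---------------------------------------------------------
    stage = "network"
    networks = {}
    try:
        if not cfg.interactions_path:
            raise ValueError("no interaction-table path configured")
        table = mio.read_interactions(cfg.interactions_path)
        netdir = outdir / "network"
        netdir.mkdir(exist_ok=True)
        for module in modules:
            try:
                g = build_interactome(module, table, anchors=cfg.anchors)
            except ValueError:
                log_lines.append(
                    f"[network] module {module.module_name!r}: empty network, skipped"
                )
                continue
            g = overlay_mirnas(g, linkage.for_module(module.module_name), module.module_name)
            sub = netdir / _safe_name(module.module_name)
            sub.mkdir(exist_ok=True)
            write_node_edge_tables(g, sub / "nodes.tsv", sub / "edges.tsv")
            write_graphml(g, str(sub / "network.graphml"))
            networks[module.module_name] = g
            hubs = top_hubs(g, 5)
            log_lines.append(
                f"[network] {module.module_name}: {g.n_nodes} nodes, "
                f"{g.n_edges} edges; top hubs: "
                + ", ".join(f"{n}({d})" for n, d in hubs)
            )
            try:
                mt = most_targeted_genes(g)
                log_lines.append(
                    f"[network] {module.module_name}: most targeted gene "
                    f"{mt[0][0]} ({mt[0][1]} miRNAs)"
                )
            except ValueError:
                pass
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e

    paths["run_log"] = str(outdir / "run_log.txt")
    with open(paths["run_log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return {
        "de": de_res,
        "enrichment": enr,
        "modules": modules,
        "linkage": linkage,
        "networks": networks,
        "paths": paths,
    }
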