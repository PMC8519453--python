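"""Pipeline orchestration: wire the stages into reproducible experiments.

A pipeline config lists named stages with parameter blocks; one global seed
deterministically derives per-stage seeds (global seed + stage index).
Stages communicate through an in-memory context and write artifacts under
the output directory; the run returns a manifest describing every stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import yaml

from . import corpus as corpus_mod
from . import embedding as emb_mod
from . import expression as expr_mod
from . import gcnn as gcnn_mod
from . import networks as net_mod
from . import synthetic as syn_mod
from . import validation as val_mod
from .errors import ConfigError, DependencyError

log = logging.getLogger(__name__)


@dataclass
class StageSpec:
    name: str
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class PipelineConfig:
    stages: list[StageSpec]
    seed: int = 0
    out_dir: Path = Path("pipeline_out")
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        stages = [StageSpec(s["name"], s.get("params", {}))
                  for s in raw.get("stages", [])]
        return cls(stages=stages, seed=int(raw.get("seed", 0)),
                   out_dir=Path(raw.get("out_dir", "pipeline_out")),
                   log_level=raw.get("log_level", "INFO"))


def _need(ctx: dict, key: str, stage: str):
    if key not in ctx:
        raise DependencyError(
            f"stage {stage!r} needs upstream artifact {key!r}")
    return ctx[key]


# -- stage implementations -------------------------------------------------

def _stage_simulate_corpus(ctx, params, seed, out_dir):
    spec = syn_mod.CorpusSpec(**{**params, "seed": seed})
    documents, truth = syn_mod.generate_corpus(spec)
    corpus_path = out_dir / "corpus.txt"
    syn_mod.write_corpus(corpus_path, documents)
    syn_path = out_dir / "synonyms.tsv"
    syn_mod.write_synonym_table(syn_path, truth)
    kb_paths = syn_mod.generate_knowledgebase(truth, out_dir / "knowledgebase")
    ctx.update(documents=documents, truth=truth)
    return {"corpus": str(corpus_path), "synonyms": str(syn_path),
            **{k: str(v) for k, v in kb_paths.items()}}


def _stage_preprocess(ctx, params, seed, out_dir):
    documents = _need(ctx, "documents", "preprocess")
    config = corpus_mod.PreprocessConfig(**params)
    table = None
    if config.substitute_synonyms:
        table = corpus_mod.load_synonym_table(out_dir / "synonyms.tsv")
    seqs = corpus_mod.preprocess_corpus(documents, config, table)
    path = out_dir / ("tokens_substituted.txt" if config.substitute_synonyms
                      else "tokens_plain.txt")
    corpus_mod.write_token_sequences(path, seqs)
    ctx["tokens"] = seqs
    ctx["synonym_table"] = table
    return {"tokens": str(path)}


def _stage_train_embed(ctx, params, seed, out_dir):
    seqs = _need(ctx, "tokens", "train_embed")
    config = emb_mod.EmbeddingConfig(**{**params, "seed": seed})
    truth = ctx.get("truth")
    type_labels = truth.entity_types if truth is not None else None
    embedding = emb_mod.train_embedding(seqs, config, type_labels)
    path = out_dir / "embedding.txt"
    emb_mod.save_embedding(embedding, path, out_dir / "embedding_types.tsv")
    ctx["embedding"] = embedding
    return {"embedding": str(path), "vocab_size": len(embedding)}


def _stage_validate(ctx, params, seed, out_dir):
    embedding = _need(ctx, "embedding", "validate")
    groups = val_mod.read_gmt(out_dir / "knowledgebase" / "gene_groups.gmt")
    summaries = val_mod.group_similarity_summary(
        embedding, groups, params.get("min_size", 2),
        params.get("max_size", 3000))
    frame = val_mod.summaries_to_frame(summaries)
    path = out_dir / "group_summaries.csv"
    frame.to_csv(path, index=False)
    ctx["group_summaries"] = summaries
    return {"group_summaries": str(path), "n_groups": len(summaries)}


def _stage_build_net(ctx, params, seed, out_dir):
    embedding = _need(ctx, "embedding", "build_net")
    threshold = params.get("threshold", 0.65)
    terms = [t for t in embedding.vocab
             if embedding.type_labels.get(t) == params.get("type", "gene")]
    network = net_mod.build_similarity_network(embedding, terms, threshold)
    main = net_mod.main_component(network)
    path = out_dir / "network_edges.tsv"
    main.write_edge_list(path)
    ctx["network"] = main
    return {"network": str(path), "vertices": main.n_vertices,
            "edges": main.n_edges}


def _stage_control_net(ctx, params, seed, out_dir):
    spec = net_mod.ControlSpec(**{**params, "seed": seed})
    reference = ctx.get("network", params.get("n"))
    if spec.mode == "k_out_random" and "n" in params:
        reference = params["n"]
    network = net_mod.make_control_network(reference, spec)
    path = out_dir / f"control_{spec.mode}.tsv"
    network.write_edge_list(path)
    ctx["control_network"] = network
    stats = net_mod.degree_statistics(network)
    return {"network": str(path), **stats}


def _stage_simulate_expression(ctx, params, seed, out_dir):
    network = ctx.get("network")
    if network is None:
        network = syn_mod.watts_strogatz_prior(
            params.pop("n_vertices", 500), seed=seed)
        ctx["network"] = network
    spec = syn_mod.ExpressionSpec(network=network, **{**params, "seed": seed})
    matrix, labels, signal = syn_mod.generate_expression(spec)
    mpath = out_dir / "expression.tsv"
    matrix.to_csv(mpath, sep="\t")
    lpath = out_dir / "labels.tsv"
    labels.to_csv(lpath, sep="\t", header=False)
    ctx["expression"] = matrix
    ctx["labels"] = labels
    return {"expression": str(mpath), "labels": str(lpath),
            "signal_genes": signal}


def _stage_prep_expr(ctx, params, seed, out_dir):
    matrix = _need(ctx, "expression", "prep_expr")
    labels = _need(ctx, "labels", "prep_expr")
    network = _need(ctx, "network", "prep_expr")
    shifted = expr_mod.nonnegative_shift(matrix)
    dataset = expr_mod.align_to_graph(shifted, network, labels)
    ctx["dataset"] = dataset
    return {"n_samples": len(dataset.samples), "n_genes": len(dataset.genes)}


def _stage_gcnn_cv(ctx, params, seed, out_dir):
    dataset = _need(ctx, "dataset", "gcnn_cv")
    arch = gcnn_mod.GCNNArchitecture(
        cheb_order=params.get("order", 7))
    config = gcnn_mod.TrainConfig(
        epochs=params.get("epochs", 100), folds=params.get("folds", 10),
        seed=seed)
    operator = gcnn_mod.build_graph_operator(dataset.graph)
    result = gcnn_mod.cross_validate(dataset, operator, arch, config)
    path = out_dir / "cv_metrics.csv"
    result.fold_metrics.to_csv(path)
    spath = out_dir / "cv_summary.csv"
    result.summary().to_csv(spath)
    ctx["cv_result"] = result
    return {"fold_metrics": str(path), "summary": str(spath),
            "mean_auc": float(result.mean["auc"])}


_STAGES: dict[str, Callable] = {
    "simulate_corpus": _stage_simulate_corpus,
    "preprocess": _stage_preprocess,
    "train_embed": _stage_train_embed,
    "validate": _stage_validate,
    "build_net": _stage_build_net,
    "control_net": _stage_control_net,
    "simulate_expression": _stage_simulate_expression,
    "prep_expr": _stage_prep_expr,
    "gcnn_cv": _stage_gcnn_cv,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the run manifest."""
    for stage in config.stages:
        if stage.name not in _STAGES:
            raise ConfigError(
                f"unknown stage {stage.name!r}; known: {sorted(_STAGES)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    ctx: dict[str, Any] = {}
    manifest: dict[str, Any] = {"seed": config.seed, "stages": []}
    for index, stage in enumerate(config.stages):
        stage_seed = config.seed + index
        log.info("stage %d: %s (seed %d)", index, stage.name, stage_seed)
        t0 = time.time()
        outputs = _STAGES[stage.name](ctx, dict(stage.params), stage_seed,
                                      out_dir)
        manifest["stages"].append({
            "name": stage.name, "params": stage.params, "seed": stage_seed,
            "outputs": outputs, "elapsed_s": round(time.time() - t0, 3)})
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["context"] = ctx
    return manifest
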