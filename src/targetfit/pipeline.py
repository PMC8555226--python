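"""End-to-end orchestration: config, logging, seeds, and the click CLI.

``run_pipeline`` drives synth (or file) inputs through centrality,
stratified comparison, degree-distribution fits, randomization with
degree-distribution projection, the bias report and the naive Bayes models,
writing every stage output as TSV/JSON into one directory together with a
manifest recording versions, per-stage seeds and output hashes.  A rerun
with the same config and seed reproduces byte-identical outputs.

Each stage's seed is derived deterministically from the global seed and the
stage name (CRC32 keyed), so stages are reproducible independently of each
other.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__, bias_scores, compare_stats, degree_dist, fitness_model
from . import graph_io, randomize as randomize_mod, synthetic_data
from .centrality import compute_centrality_table
from .project import ProjectionSpec, project_onto_scalefree, select_matched_random_sets

logger = logging.getLogger(__name__)

CONFIG_KEYS = {
    "graph", "annotations", "gaf", "score_cutoff", "synth", "metrics",
    "classes", "alpha", "include_path_metrics", "fit_range", "randomize",
    "model", "out_dir", "seed",
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    graph: str | None = None
    annotations: str | None = None
    gaf: str | None = None
    score_cutoff: float | None = None
    synth: dict | None = None
    metrics: list | None = None
    classes: list | None = None
    alpha: float = 0.05
    include_path_metrics: bool = True
    fit_range: tuple = (100, 1000)
    randomize: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    out_dir: str = "targetfit_out"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.graph is None and self.synth is None:
            raise ValueError("config needs either 'graph' or 'synth'")


def validate_config(path: str | Path) -> PipelineConfig:
    """Parse, default and validate a YAML pipeline config."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    unknown = sorted(set(raw) - CONFIG_KEYS)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    if "fit_range" in raw:
        raw["fit_range"] = tuple(raw["fit_range"])
    cfg = PipelineConfig(**raw)
    if cfg.synth is not None:
        synthetic_data.SynthConfig(**{**cfg.synth, "seed": stage_seed(cfg.seed, "synth")})
    ws = cfg.randomize.get("ws")
    if ws and ws.get("k", 0) % 2:
        raise ValueError("Watts-Strogatz K must be even")
    return cfg


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


def _load_inputs(cfg: PipelineConfig):
    if cfg.synth is not None:
        scfg = synthetic_data.SynthConfig(
            **{**cfg.synth, "seed": stage_seed(cfg.seed, "synth")}
        )
        return synthetic_data.synth_study(scfg)
    path = Path(cfg.graph)
    if not path.exists():
        raise FileNotFoundError(f"graph input not found: {path}")
    if cfg.score_cutoff is not None:
        graph = graph_io.read_string_links(path, cfg.score_cutoff)
    else:
        graph = graph_io.read_edge_list(path, "sif" if path.suffix == ".sif" else "tsv2col")
    if cfg.annotations:
        ann = graph_io.read_annotations(cfg.annotations, graph)
    else:
        ann = graph_io.empty_annotations(graph.nodes())
    if cfg.gaf:
        gaf = graph_io.read_gaf(cfg.gaf)
        ann["go_terms"] = [
            gaf.get(str(n), frozenset()) | terms
            for n, terms in zip(ann.index, ann["go_terms"])
        ]
    return graph, ann


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage; returns the output directory (with manifest.json)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: v for k, v in asdict(cfg).items()},
        "stages": {},
    }

    def record(stage, name, path: Path):
        outputs[name] = str(path)
        manifest["stages"].setdefault(stage, {})[name] = _sha256(path)

    try:
        graph, ann = _load_inputs(cfg)
        graph_io.write_edge_list(graph, out / "graph.tsv")
        graph_io.write_annotations(ann, out / "annotations.tsv")
        record("inputs", "graph", out / "graph.tsv")
        record("inputs", "annotations", out / "annotations.tsv")

        table = compute_centrality_table(graph, cfg.include_path_metrics)
        table.to_csv(out / "centrality.tsv", sep="\t")
        record("centrality", "table", out / "centrality.tsv")

        matrix = compare_stats.stratified_comparison(
            table, ann, metrics=cfg.metrics, classes=cfg.classes, alpha=cfg.alpha
        )
        matrix.to_csv(out / "comparison.tsv", sep="\t", index=False)
        record("compare", "matrix", out / "comparison.tsv")

        dist = degree_dist.empirical_distribution(graph)
        fits = {}
        try:
            simple = degree_dist.fit_simple_powerlaw(dist, *cfg.fit_range)
            fits["simple"] = asdict(simple)
        except ValueError as exc:
            fits["simple"] = {"error": str(exc)}
        sat = degree_dist.fit_saturated_powerlaw(
            dist, seed=stage_seed(cfg.seed, "degree_fit")
        )
        sat.fit_p = degree_dist.fit_quality_by_simulation(
            sat, dist, n_sim=200, seed=stage_seed(cfg.seed, "fit_quality")
        )
        fits["saturated"] = asdict(sat)
        with open(out / "degree_fit.json", "w") as handle:
            json.dump(fits, handle, indent=2, default=_json_default)
        record("degree_fit", "fits", out / "degree_fit.json")

        rand_report = _randomization_stage(cfg, graph, ann, table, out)
        with open(out / "randomization.json", "w") as handle:
            json.dump(rand_report, handle, indent=2, default=_json_default)
        record("randomize", "report", out / "randomization.json")

        _bias_stage(table, ann, out)
        record("bias", "citations", out / "bias_citations.tsv")
        record("bias", "correlations", out / "bias_correlations.tsv")
        record("bias", "hybrid_scores", out / "hybrid_scores.tsv")

        model_report = _model_stage(cfg, table, ann)
        with open(out / "model_report.json", "w") as handle:
            json.dump(model_report, handle, indent=2, default=_json_default)
        record("model", "report", out / "model_report.json")
    except Exception as exc:
        manifest["error"] = repr(exc)
        with open(out / "manifest.json", "w") as handle:
            json.dump(manifest, handle, indent=2, default=_json_default)
        raise
    with open(out / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2, default=_json_default)
    return out


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    return str(obj)


def _randomization_stage(cfg, graph, ann, table, out: Path) -> dict:
    n = graph.number_of_nodes()
    m = graph.number_of_edges()
    if n < 10 or m < 10:
        return {"skipped": "graph too small"}
    seed = stage_seed(cfg.seed, "randomize")
    degrees = np.array([d for _, d in graph.degree()], dtype=float)
    mean_k = max(int(round(degrees.mean())), 2)
    report: dict = {}
    shuffled = randomize_mod.degree_preserving_shuffle(
        graph, cfg.randomize.get("swaps_per_edge", 10.0), seed=seed
    )
    report["degree_preserving_edges"] = shuffled.number_of_edges()
    ba = randomize_mod.generate_ba(n, max(mean_k // 2, 1), seed=seed + 1)
    er = randomize_mod.generate_er(n, m, seed=seed + 2)
    ws_k = mean_k if mean_k % 2 == 0 else mean_k + 1
    ws = randomize_mod.generate_ws(n, ws_k, cfg.randomize.get("ws_beta", 0.25), seed=seed + 3)
    report["null_edges"] = {
        "ba": ba.number_of_edges(), "er": er.number_of_edges(), "ws": ws.number_of_edges()
    }
    report["percentile_ratios"] = {
        "observed": randomize_mod.percentile_ratio_comparison(graph, 10, 90, seed=seed + 4),
        "ba": randomize_mod.percentile_ratio_comparison(ba, 10, 90, seed=seed + 5),
        "er": randomize_mod.percentile_ratio_comparison(er, 10, 90, seed=seed + 6),
    }
    p4 = ann.index[ann["target_status"] == "phase4"]
    if len(p4) >= 3:
        src_degrees = [graph.degree(v) for v in p4]
        proj = project_onto_scalefree(src_degrees, ba, seed=seed + 7)
        report["projection_ba"] = {
            "achieved_mean": proj.achieved_mean, "achieved_sd": proj.achieved_sd
        }
        spec = ProjectionSpec(seed=seed + 8, k_max_source=float(degrees.max()))
        try:
            matched = select_matched_random_sets(src_degrees, er, spec)
            report["projection_er"] = {
                "achieved_mean": matched.achieved_mean,
                "achieved_sd": matched.achieved_sd,
                "target_mean": matched.target_mean,
                "target_sd": matched.target_sd,
                "shapiro_p": matched.shapiro_p,
                "tries": matched.tries,
            }
        except RuntimeError as exc:
            report["projection_er"] = {"error": str(exc)}
    return report


def _bias_stage(table, ann, out: Path) -> None:
    bias_scores.citation_enrichment(ann).to_csv(out / "bias_citations.tsv", sep="\t")
    try:
        corr = bias_scores.centrality_citation_correlation(table, ann)
    except ValueError:
        corr = pd.Series(dtype=float, name="spearman_r2")
    corr.to_frame().to_csv(out / "bias_correlations.tsv", sep="\t")
    bias_scores.hybrid_scores(table, ann).to_csv(out / "hybrid_scores.tsv", sep="\t")
    if any(len(t) for t in ann["go_terms"]):
        bias_scores.go_enrichment(ann).to_csv(out / "go_enrichment.tsv", sep="\t")


def _model_stage(cfg, table, ann) -> dict:
    feature_cols = cfg.model.get(
        "features",
        [c for c in table.columns
         if c not in ("component", "component_diameter", "eccentricity", "stress")],
    )
    features = table[feature_cols].dropna()
    spec = fitness_model.ModelSpec(
        features=list(features.columns),
        scope="per_class",
        selection=cfg.model.get("selection", "forward"),
        seed=stage_seed(cfg.seed, "model"),
    )
    try:
        suite = fitness_model.per_class_suite(features, ann.reindex(features.index), spec)
    except ValueError as exc:
        return {"skipped": str(exc)}

    def report_dict(rep: fitness_model.ModelReport) -> dict:
        return {
            "features": rep.features,
            "tp": rep.tp, "fp": rep.fp, "fn": rep.fn, "tn": rep.tn,
            "phase4_recall": rep.phase4_recall,
            "other_f1": rep.other_f1,
            "accuracy": rep.accuracy,
            "predicted": list(rep.predicted),
        }

    return {
        "network_wide": report_dict(suite["network_wide"]),
        "per_class": {cls: report_dict(r) for cls, r in suite["per_class"].items()},
        "rescued": list(suite["rescued"]),
    }


# --------------------------------------------------------------------------
# CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Enable debug logging.")
def main(verbose: bool):
    """Network-centrality analysis of drug-target fitness."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


@main.command("run-all")
@click.option("--config", "config_path", required=True, type=click.Path(exists=True))
def run_all_cmd(config_path):
    """Run the full pipeline from a YAML config."""
    cfg = validate_config(config_path)
    out = run_pipeline(cfg)
    click.echo(f"pipeline outputs in {out}")


@main.command("synth")
@click.option("--n", default=2000, show_default=True)
@click.option("--model", default="configuration", show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_dir", required=True, type=click.Path())
def synth_cmd(n, model, seed, out_dir):
    """Generate a synthetic study bundle."""
    cfg = synthetic_data.SynthConfig(n_nodes=n, model=model, seed=seed)
    graph, _ = synthetic_data.synth_study(cfg, out_dir)
    click.echo(f"{graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges -> {out_dir}")


@main.command("centrality")
@click.option("--in", "graph_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
@click.option("--no-path-metrics", is_flag=True)
def centrality_cmd(graph_path, out_path, no_path_metrics):
    """Compute the per-node centrality table from an edge-list TSV."""
    graph = graph_io.read_edge_list(graph_path)
    compute_centrality_table(graph, not no_path_metrics).to_csv(out_path, sep="\t")
    click.echo(out_path)


@main.command("compare")
@click.option("--metrics", "metrics_path", required=True, type=click.Path(exists=True))
@click.option("--annotations", "ann_path", required=True, type=click.Path(exists=True))
@click.option("--graph", "graph_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_path", required=True, type=click.Path())
def compare_cmd(metrics_path, ann_path, graph_path, out_path):
    """Stratified phase4 vs all-target comparison from saved tables."""
    graph = graph_io.read_edge_list(graph_path)
    table = pd.read_csv(metrics_path, sep="\t", index_col=0)
    ann = graph_io.read_annotations(ann_path, graph)
    matrix = compare_stats.stratified_comparison(table, ann)
    matrix.to_csv(out_path, sep="\t", index=False)
    click.echo(out_path)


@main.command("fitdegree")
@click.option("--in", "graph_path", required=True, type=click.Path(exists=True))
@click.option("--range", "fit_range", nargs=2, type=float, default=(100, 1000))
@click.option("--saturated", is_flag=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def fitdegree_cmd(graph_path, fit_range, saturated, seed, out_path):
    """Fit the degree distribution of an edge-list network."""
    graph = graph_io.read_edge_list(graph_path)
    dist = degree_dist.empirical_distribution(graph)
    if saturated:
        fit = degree_dist.fit_saturated_powerlaw(dist, seed=seed)
    else:
        fit = degree_dist.fit_simple_powerlaw(dist, *fit_range)
    with open(out_path, "w") as handle:
        json.dump(asdict(fit), handle, indent=2, default=_json_default)
    click.echo(out_path)


@main.command("randomize")
@click.option("--model", type=click.Choice(["dp", "ba", "er", "ws"]), required=True)
@click.option("--in", "graph_path", type=click.Path(exists=True))
@click.option("--n", type=int)
@click.option("--m", type=int, help="edges (er) or edges per node (ba)")
@click.option("--k", type=int, help="ring neighbors (ws)")
@click.option("--beta", type=float, default=0.25, show_default=True)
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def randomize_cmd(model, graph_path, n, m, k, beta, seed, out_path):
    """Generate a null-model network as a 2-column TSV."""
    if model == "dp":
        graph = randomize_mod.degree_preserving_shuffle(
            graph_io.read_edge_list(graph_path), seed=seed
        )
    elif model == "ba":
        graph = randomize_mod.generate_ba(n, m, seed=seed)
    elif model == "er":
        graph = randomize_mod.generate_er(n, m, seed=seed)
    else:
        graph = randomize_mod.generate_ws(n, k, beta, seed=seed)
    graph_io.write_edge_list(graph, out_path)
    click.echo(f"{graph.number_of_edges()} edges -> {out_path}")


@main.command("bias")
@click.option("--metrics", "metrics_path", required=True, type=click.Path(exists=True))
@click.option("--annotations", "ann_path", required=True, type=click.Path(exists=True))
@click.option("--graph", "graph_path", required=True, type=click.Path(exists=True))
@click.option("--out", "out_dir", required=True, type=click.Path())
def bias_cmd(metrics_path, ann_path, graph_path, out_dir):
    """Write the knowledge-bias report (citations, correlations, scores)."""
    graph = graph_io.read_edge_list(graph_path)
    table = pd.read_csv(metrics_path, sep="\t", index_col=0)
    ann = graph_io.read_annotations(ann_path, graph)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _bias_stage(table, ann, out)
    click.echo(str(out))


@main.command("train")
@click.option("--metrics", "metrics_path", required=True, type=click.Path(exists=True))
@click.option("--annotations", "ann_path", required=True, type=click.Path(exists=True))
@click.option("--graph", "graph_path", required=True, type=click.Path(exists=True))
@click.option("--seed", default=0, show_default=True)
@click.option("--out", "out_path", required=True, type=click.Path())
def train_cmd(metrics_path, ann_path, graph_path, seed, out_path):
    """Train the per-class naive Bayes suite and write the model report."""
    graph = graph_io.read_edge_list(graph_path)
    table = pd.read_csv(metrics_path, sep="\t", index_col=0)
    ann = graph_io.read_annotations(ann_path, graph)
    cfg = PipelineConfig(graph=graph_path, seed=seed)
    report = _model_stage(cfg, table, ann)
    with open(out_path, "w") as handle:
        json.dump(report, handle, indent=2, default=_json_default)
    click.echo(out_path)


if __name__ == "__main__":
    main()
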