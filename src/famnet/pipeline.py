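"""End-to-end orchestration: one config in, a reproducible report bundle out.

Stage order: sequence family → network build/merge → first-neighbor
extraction → topology → expression integration → enrichment →
subcellular layers and path enumeration. Stages whose inputs are absent
from the config are skipped with a logged notice; each stage writes its
outputs as it completes, so any stage can be re-run standalone from the
previous stage's serialized files. A run manifest (config echo + hash,
seed, package version) makes the run reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from . import enrichment as enr
from . import expression as expr
from . import family as fam
from . import ppi_io
from . import seqfam
from . import subcellular as subcell
from . import topology as topo

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    out_dir: str = "famnet_out"
    seed: int = 0
    edges: list[dict] = field(default_factory=list)  # [{path, dialect}]
    seeds_path: str | None = None
    expression_path: str | None = None
    groups_path: str | None = None
    terms_path: str | None = None
    localizations_path: str | None = None
    sequences_path: str | None = None
    alignment_path: str | None = None
    tumor_groups: list[str] = field(default_factory=list)
    reference_group: str | None = None
    path_endpoints: list[list[str]] = field(default_factory=list)
    n_subgroups: int = 2
    r_threshold: float = 0.8
    correlation_alpha: float = 0.05
    p_cutoff_map: float = 0.05
    overlap_cutoff: float = 0.6
    p_cutoff_kappa: float = 0.01
    kappa_threshold: float = 0.3
    conservation_tau: float = 0.9
    conservation_min_width: int = 5
    strict_parse: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of problems; empty means the config is runnable."""
    errors: list[str] = []
    for spec in cfg.edges:
        p = spec.get("path")
        if p is None or not Path(p).exists():
            errors.append(f"edges path missing or nonexistent: {p}")
        if spec.get("dialect", "plain") not in ppi_io.DIALECTS:
            errors.append(f"unknown dialect: {spec.get('dialect')}")
    for name in ("seeds_path", "expression_path", "groups_path", "terms_path",
                 "localizations_path", "sequences_path", "alignment_path"):
        p = getattr(cfg, name)
        if p is not None and not Path(p).exists():
            errors.append(f"{name} does not exist: {p}")
    for name in (
        "r_threshold", "correlation_alpha", "p_cutoff_map", "overlap_cutoff",
        "p_cutoff_kappa", "kappa_threshold", "conservation_tau",
    ):
        v = getattr(cfg, name)
        if not 0 < v < 1:
            errors.append(f"{name} out of range (0, 1): {v}")
    if (cfg.expression_path is None) != (cfg.groups_path is None):
        errors.append("expression_path and groups_path must be given together")
    if cfg.tumor_groups and cfg.reference_group is None:
        errors.append("tumor_groups given without reference_group")
    return errors


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns a summary dict (the manifest).

    Any stage failure aborts with the stage name and offending input in
    the exception message.
    """
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, **outputs: Path) -> None:
        manifest["stages"].append(stage)
        for k, v in outputs.items():
            manifest["outputs"][k] = str(v)

    # ---- sequence family -------------------------------------------------
    if cfg.sequences_path:
        _stage("seqfam")
        try:
            seqs = seqfam.read_fasta(cfg.sequences_path)
            matrix = seqfam.identity_matrix(seqs)
            matrix.to_tsv(out / "identity_matrix.tsv")
            if len(seqs) > 1:
                clustering = seqfam.cluster_family(matrix, k=cfg.n_subgroups)
                (out / "family_dendrogram.nwk").write_text(clustering.to_newick() + "\n")
                with open(out / "family_subgroups.tsv", "w") as fh:
                    fh.write("member\tsubgroup\n")
                    for m in sorted(clustering.assignment):
                        fh.write(f"{m}\t{clustering.assignment[m]}\n")
            if cfg.alignment_path:
                aln = seqfam.read_fasta(cfg.alignment_path)
                blocks = seqfam.detect_conserved_blocks(
                    aln, tau=cfg.conservation_tau, min_width=cfg.conservation_min_width
                )
                with open(out / "conserved_blocks.tsv", "w") as fh:
                    fh.write("start\tend\twidth\tconservation\n")
                    for b in blocks:
                        fh.write(f"{b.start}\t{b.end}\t{b.width}\t{b.conservation:.6f}\n")
        except Exception as e:
            raise RuntimeError(f"stage seqfam failed on {cfg.sequences_path}: {e}") from e
        record("seqfam", identity_matrix=out / "identity_matrix.tsv")
    else:
        logger.info("no sequences configured; seqfam skipped")

    # ---- build / merge ---------------------------------------------------
    if not cfg.edges:
        raise ValueError("stage build: no edge lists configured")
    _stage("build")
    try:
        pair_lists, sources = [], []
        for spec in cfg.edges:
            dialect = ppi_io.DIALECTS[spec.get("dialect", "plain")]
            pair_lists.append(
                ppi_io.read_edge_list(spec["path"], dialect, strict=cfg.strict_parse)
            )
            sources.append(Path(spec["path"]).stem)
        parent = ppi_io.merge_networks(*pair_lists, sources=sources)
    except Exception as e:
        raise RuntimeError(f"stage build failed: {e}") from e
    ppi_io.export_graphml(parent, out / "parent.graphml")
    record("build", parent_graphml=out / "parent.graphml")

    # ---- extract ---------------------------------------------------------
    graph = parent
    if cfg.seeds_path:
        _stage("extract")
        try:
            seed_symbols = fam.read_seed_list(cfg.seeds_path)
            seed_set = fam.map_seeds(parent, seed_symbols)
            graph = fam.extract_first_neighbor_subnetwork(parent, seed_set)
            census = fam.subnetwork_census(graph)
        except Exception as e:
            raise RuntimeError(f"stage extract failed on {cfg.seeds_path}: {e}") from e
        with open(out / "census.tsv", "w") as fh:
            fh.write("nodes\tedges\tseeds\tneighbors\tunmapped_seeds\n")
            fh.write(
                f"{census.nodes}\t{census.edges}\t{census.seeds}\t{census.neighbors}\t"
                + ",".join(sorted(seed_set.unmapped))
                + "\n"
            )
        record("extract", census=out / "census.tsv")
    else:
        logger.info("no seeds configured; running downstream on the full network")

    # ---- topology --------------------------------------------------------
    _stage("topology")
    try:
        summary = topo.summary_statistics(graph)
        dist = topo.degree_distribution(graph)
        fit = topo.fit_power_law(dist) if len(dist.points) >= 2 else None
    except Exception as e:
        raise RuntimeError(f"stage topology failed: {e}") from e
    report = {
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "diameter": summary.diameter,
        "density": summary.density,
        "centralization": summary.centralization,
        "heterogeneity": summary.heterogeneity,
        "mean_clustering": summary.mean_clustering,
        "degree_distribution": [list(p) for p in dist.points],
        "power_law": None
        if fit is None
        else {"a": fit.a, "beta": fit.beta, "r_squared": fit.r_squared},
    }
    (out / "topology.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    summary.node_table.to_csv(out / "topology_nodes.tsv", sep="\t")
    record("topology", topology=out / "topology.json", topology_nodes=out / "topology_nodes.tsv")

    # ---- expression ------------------------------------------------------
    matrix = None
    if cfg.expression_path:
        _stage("express")
        try:
            matrix = expr.read_expression(cfg.expression_path, cfg.groups_path)
            graph = expr.weight_edges(
                graph,
                matrix,
                group=None,
                tumor_groups=tuple(cfg.tumor_groups),
                reference_group=cfg.reference_group,
            )
            for tumor in cfg.tumor_groups:
                fcs = expr.fold_changes(matrix, tumor, cfg.reference_group)
                with open(out / f"fold_changes_{tumor}.tsv", "w") as fh:
                    fh.write("gene\tlog2fc\tfold\tdirection\tsigned_fold\n")
                    for f in fcs:
                        fh.write(
                            f"{f.gene}\t{f.log2fc:.6f}\t{f.fold:.6f}\t{f.direction}\t"
                            f"{f.signed_fold:.6f}\n"
                        )
            if cfg.seeds_path:
                seed_genes = [n for n, d in graph.nodes(data=True) if d.get("is_seed")]
                for grp in cfg.tumor_groups or [None]:
                    present = [g for g in seed_genes if g in matrix.values.index]
                    if len(present) >= 2:
                        ana = expr.correlation_matrix(
                            matrix, sorted(present), group=grp,
                            r_threshold=cfg.r_threshold, alpha=cfg.correlation_alpha,
                        )
                        tag = grp if grp is not None else "all"
                        ana.matrix.to_csv(out / f"correlation_{tag}.tsv", sep="\t")
                        ana.pairs.to_csv(out / f"correlated_pairs_{tag}.tsv", sep="\t", index=False)
        except Exception as e:
            raise RuntimeError(f"stage express failed on {cfg.expression_path}: {e}") from e
        record("express")
    else:
        logger.info("no expression configured; express skipped")

    # ---- enrichment ------------------------------------------------------
    if cfg.terms_path and cfg.seeds_path:
        _stage("enrich")
        try:
            terms, _desc = enr.read_gmt(cfg.terms_path)
            universe = set(map(str, parent.nodes()))
            query = [n for n, d in graph.nodes(data=True) if d.get("is_seed")]
            results = enr.enrich(query, terms, universe)
            tn_cfg = enr.TermNetworkConfig(
                p_cutoff_map=cfg.p_cutoff_map,
                overlap_cutoff=cfg.overlap_cutoff,
                p_cutoff_kappa=cfg.p_cutoff_kappa,
                kappa_threshold=cfg.kappa_threshold,
            )
            with open(out / "enrichment.tsv", "w") as fh:
                fh.write("term\tnamespace\tK\tn\tk\tp\tp_adj\tgenes\n")
                for r in results:
                    fh.write(
                        f"{r.term}\t{r.namespace}\t{r.K}\t{r.n}\t{r.k}\t"
                        f"{r.p:.6g}\t{r.p_adj:.6g}\t{','.join(r.genes)}\n"
                    )
            ppi_io.export_graphml(enr.enrichment_map(results, terms, tn_cfg), out / "enrichment_map.graphml")
            ppi_io.export_graphml(
                enr.kappa_term_network(results, terms, universe, tn_cfg),
                out / "kappa_terms.graphml",
            )
        except Exception as e:
            raise RuntimeError(f"stage enrich failed on {cfg.terms_path}: {e}") from e
        record("enrich", enrichment=out / "enrichment.tsv")
    else:
        logger.info("terms or seeds missing; enrich skipped")

    # ---- layers / paths --------------------------------------------------
    if cfg.localizations_path:
        _stage("layers")
        try:
            annotations = subcell.read_localizations(cfg.localizations_path)
            layer_of = subcell.assign_layers(graph, annotations)
            layout = subcell.layered_layout(graph, layer_of)
            with open(out / "layout.tsv", "w") as fh:
                fh.write("node\tlayer\tx\ty\n")
                for n in sorted(graph.nodes(), key=str):
                    x, y = layout[n]
                    fh.write(f"{n}\t{layer_of.get(str(n), 'unknown')}\t{x:.6f}\t{y:.6f}\n")
            for source, target in cfg.path_endpoints:
                records = subcell.all_shortest_paths(graph, source, target, layers=layer_of)
                subcell.write_path_report(records, out / f"paths_{source}_{target}.tsv")
        except Exception as e:
            raise RuntimeError(
                f"stage layers failed on {cfg.localizations_path}: {e}"
            ) from e
        record("layers", layout=out / "layout.tsv")
    else:
        logger.info("no localizations configured; layers skipped")

    ppi_io.export_graphml(graph, out / "network.graphml")
    ppi_io.export_node_attributes(graph, out / "node_attributes.tsv")
    ppi_io.export_edge_attributes(graph, out / "edge_attributes.tsv")
    record("export", network=out / "network.graphml")

    manifest["config_hash"] = hashlib.sha256(
        json.dumps(asdict(cfg), sort_keys=True).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
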