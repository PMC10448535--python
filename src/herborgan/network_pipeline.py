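"""Role-typed network assembly and end-to-end pipeline orchestration.

The run proceeds screen → targets → core → enrich (on the full target union)
and link (on the core set) → networks, writing every intermediate artifact
plus a machine-readable JSON report of all counts and the effective
configuration.  Given the same config and inputs the report is byte-stable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx

from . import compound_screen, io_formats, organ_enrichment, ppi_core, target_aggregate
from . import expression_linking as xl
from .errors import FormatError, PipelineStageError, PipelineUsageError, StructureError

logger = logging.getLogger(__name__)

#: undirected role pairs an edge may connect
_ALLOWED_ROLE_PAIRS = {
    frozenset({"compound", "gene"}),
    frozenset({"gene", "tissue"}),
    frozenset({"gene", "organ-group"}),
}


def build_role_graph(
    edge_sets: Iterable[tuple[str, str, Iterable[tuple[str, str]]]],
    keep_isolated: bool = False,
    isolated_nodes: Iterable[tuple[str, str]] = (),
) -> nx.Graph:
    """Merge typed edge lists into one role-annotated graph.

    ``edge_sets`` items are ``(role_a, role_b, pairs)``; every edge must
    connect adjacent roles (compound–gene, gene–tissue, gene–organ-group) and
    a node may carry only one role.  Node ``degree`` attributes are computed
    after merging.  ``isolated_nodes`` (``(name, role)`` pairs) are added only
    when ``keep_isolated``.
    """
    g = nx.Graph()

    def _set_role(node: str, role: str) -> None:
        existing = g.nodes[node].get("role") if node in g else None
        if existing is not None and existing != role:
            raise StructureError(
                f"node {node!r} appears with conflicting roles {existing!r} and {role!r}"
            )
        g.add_node(node, role=role)

    for role_a, role_b, pairs in edge_sets:
        if frozenset({role_a, role_b}) not in _ALLOWED_ROLE_PAIRS:
            raise StructureError(f"edges between roles {role_a!r} and {role_b!r} are not allowed")
        for a, b in pairs:
            if a == b:
                raise StructureError(f"self-edge on node {a!r}")
            _set_role(a, role_a)
            _set_role(b, role_b)
            g.add_edge(a, b)
    if keep_isolated:
        for name, role in isolated_nodes:
            _set_role(name, role)
    for n in g.nodes:
        g.nodes[n]["degree"] = int(g.degree(n))
    return g


_CONFIG_FIELDS: dict[str, type] = {}


@dataclass
class RunConfig:
    """All thresholds and input paths for one pipeline run.

    Serializes to a flat ``key = value`` text file; unknown keys in a config
    file are errors.
    """

    compounds: str = ""
    associations: str = ""
    ppi: str = ""
    catalog: str = ""
    atlas_mean: str = ""
    atlas_z_a: str = ""
    atlas_z_b: str = ""
    grouping: str = ""
    universe: str = ""
    out_dir: str = "results"
    ob_min: float = 30.0
    dl_min: float = 0.18
    levels: str = "A,B,C"
    score_cutoff: float = 30.0
    min_score: float = 0.9
    multiplier: float = 2.0
    method: str = "midp"
    test_depletion: bool = True
    alpha: float = 0.05
    ddof: int = 1
    enrich_enabled: bool = True
    enrich_on: str = "union"
    link_on: str = "core"
    restrict_to_active: bool = True
    keep_isolated: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise PipelineUsageError("alpha must lie in (0, 1)")
        if self.min_score < 0 or self.min_score > 1:
            raise PipelineUsageError("min_score must lie in [0, 1]")
        if self.multiplier <= 0:
            raise PipelineUsageError("multiplier must be positive")
        if self.ddof not in (0, 1):
            raise PipelineUsageError("ddof must be 0 or 1")
        if self.enrich_on not in ("union", "core"):
            raise PipelineUsageError("enrich_on must be 'union' or 'core'")
        if self.link_on not in ("union", "core"):
            raise PipelineUsageError("link_on must be 'union' or 'core'")
        if self.method not in organ_enrichment.METHODS:
            raise PipelineUsageError(f"method must be one of {organ_enrichment.METHODS}")

    @property
    def allowed_levels(self) -> frozenset[str]:
        return frozenset(s.strip().upper() for s in self.levels.split(",") if s.strip())

    def to_file(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        types = {f.name: type(getattr(cls(), f.name)) for f in dataclasses.fields(cls)}
        kwargs: dict[str, object] = {}
        with open(path, encoding="utf-8") as fh:
            for line_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise FormatError(f"config {path}, line {line_no}: expected key = value")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in fields:
                    raise FormatError(f"config {path}, line {line_no}: unknown key {key!r}")
                typ = types[key]
                try:
                    if typ is bool:
                        if value.lower() not in ("true", "false"):
                            raise ValueError(value)
                        kwargs[key] = value.lower() == "true"
                    else:
                        kwargs[key] = typ(value)
                except ValueError:
                    raise FormatError(
                        f"config {path}, line {line_no}: bad value {value!r} for {key!r}"
                    ) from None
        return cls(**kwargs)


def _write_enrichment_tsv(results, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("term\tk\tK\tn\tN\tfold\tdirection\tp_raw\tp_adj\tsignificant\n")
        for r in results:
            c = r.counts
            fh.write(
                f"{r.term}\t{c.k}\t{c.K}\t{c.n}\t{c.N}\t{r.fold:.6g}\t{r.direction}\t"
                f"{r.p_raw:.6g}\t{r.p_adj:.6g}\t{str(r.significant).lower()}\n"
            )


def _write_ranking_tsv(ranking: list[tuple[str, int]], path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("tissue\tdegree\n")
        for tissue, degree in ranking:
            fh.write(f"{tissue}\t{degree}\n")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full run; return (and write) the machine-readable report.

    Any stage failure aborts with the stage name and cause, after removing the
    partial outputs written so far.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    report: dict = {"stages": {}, "counts": {}}
    stage = "screen"
    try:
        # --- screen -------------------------------------------------------
        raw = io_formats.read_compound_table(config.compounds)
        deduped = compound_screen.dedup_compounds(raw)
        actives = compound_screen.adme_filter(deduped, config.ob_min, config.dl_min)
        multi = compound_screen.cross_source_overlap(deduped)
        io_formats.write_compound_table(actives, _track(out / "screened_compounds.tsv"))
        report["counts"]["compounds"] = {
            "input_rows": len(raw),
            "deduplicated": len(deduped),
            "active": len(actives),
            "multi_source": len(multi),
        }
        report["stages"]["screen"] = "ok"
        active_keys = {r.name for r in actives} | {str(r.cid) for r in actives if r.cid}

        # --- targets ------------------------------------------------------
        stage = "targets"
        assocs = io_formats.read_association_table(config.associations)
        passed = target_aggregate.filter_associations(
            assocs, config.allowed_levels, config.score_cutoff
        )
        if config.restrict_to_active:
            passed = [a for a in passed if a.compound_key in active_keys]
        union = target_aggregate.union_targets(passed)
        pairs = target_aggregate.compound_target_map(passed)
        io_formats.write_gene_list(union.genes, _track(out / "targets.txt"))
        with open(_track(out / "compound_gene.tsv"), "w", encoding="utf-8", newline="\n") as fh:
            fh.write("compound\tgene\n")
            for c, g in pairs:
                fh.write(f"{c}\t{g}\n")
        report["counts"]["targets"] = {
            "input_rows": len(assocs),
            "pass_rows": len(passed),
            "per_source": union.per_source,
            "union": len(union),
            "compound_gene_pairs": len(pairs),
        }
        report["stages"]["targets"] = "ok"

        # --- core ---------------------------------------------------------
        stage = "core"
        edge_rows = io_formats.read_edge_list(config.ppi)
        network = ppi_core.build_network(edge_rows, config.min_score, restrict_to=union.genes)
        network = ppi_core.drop_isolated(network)
        core = ppi_core.select_core(network, config.multiplier)
        degrees = dict(network.graph.degree())
        io_formats.write_gene_list(core, _track(out / "core_targets.txt"))
        with open(_track(out / "degree_table.tsv"), "w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene\tdegree\n")
            for gene, degree in network.degree_table():
                fh.write(f"{gene}\t{degree}\n")
        for n in network.graph.nodes:
            network.graph.nodes[n]["degree"] = int(degrees[n])
            network.graph.nodes[n]["role"] = "gene"
        io_formats.write_graph(network.graph, "graphml", _track(out / "ppi_network.graphml"))
        report["counts"]["core"] = {
            "network_nodes": len(network),
            "network_edges": network.graph.number_of_edges(),
            "mean_degree": round(sum(degrees.values()) / max(len(degrees), 1), 4),
            "core_targets": len(core),
        }
        report["stages"]["core"] = "ok"

        # --- enrich -------------------------------------------------------
        stage = "enrich"
        if config.enrich_enabled and config.catalog:
            catalog = io_formats.read_catalog(
                config.catalog, universe_path=config.universe or None
            )
            enrich_genes = core if config.enrich_on == "core" else list(union.genes)
            results = organ_enrichment.enrich_catalog(
                enrich_genes,
                catalog,
                method=config.method,
                test_depletion=config.test_depletion,
                alpha=config.alpha,
            )
            _write_enrichment_tsv(results, _track(out / "enrichment.tsv"))
            sig = [r for r in results if r.significant]
            report["counts"]["enrichment"] = {
                "tested": len(results),
                "significant": len(sig),
                "significant_enriched": sum(1 for r in sig if r.direction == "enriched"),
                "significant_depleted": sum(1 for r in sig if r.direction == "depleted"),
                "top_term": results[0].term if results else None,
            }
            report["stages"]["enrich"] = "ok"
        else:
            report["stages"]["enrich"] = "skipped"

        # --- link ---------------------------------------------------------
        stage = "link"
        link_genes = core if config.link_on == "core" else list(union.genes)
        grouping = (
            io_formats.read_grouping(config.grouping)
            if config.grouping
            else xl.default_organ_grouping()
        )
        link_counts: dict = {}
        assignments: dict[str, str] = {}
        mean_links = z_links = None
        if config.atlas_mean:
            atlas = io_formats.read_expression_matrix(config.atlas_mean)
            atlas = xl.ExpressionAtlas(atlas.frame.loc[atlas.frame.index.isin(link_genes)])
            mean_links = xl.link_above_mean(atlas)
            _write_ranking_tsv(
                xl.organ_degree_ranking(mean_links), _track(out / "ranking_mean.tsv")
            )
            assignments = xl.assign_top_group(atlas, grouping)
            with open(_track(out / "gene_groups.tsv"), "w", encoding="utf-8", newline="\n") as fh:
                fh.write("gene\tgroup\n")
                for gene in sorted(assignments):
                    fh.write(f"{gene}\t{assignments[gene]}\n")
            group_sizes: dict[str, int] = {}
            for grp in assignments.values():
                group_sizes[grp] = group_sizes.get(grp, 0) + 1
            link_counts["mean_rule_edges"] = len(mean_links)
            link_counts["grouped_genes"] = len(assignments)
            link_counts["group_sizes"] = dict(sorted(group_sizes.items()))
        if config.atlas_z_a:
            za = io_formats.read_expression_matrix(config.atlas_z_a)
            if config.atlas_z_b:
                zb = io_formats.read_expression_matrix(config.atlas_z_b)
                za = xl.consensus_max(za, zb)
            za = xl.ExpressionAtlas(za.frame.loc[za.frame.index.isin(link_genes)])
            z = xl.zscore_rows(za, ddof=config.ddof)
            z_links = xl.link_positive_z(z)
            _write_ranking_tsv(xl.organ_degree_ranking(z_links), _track(out / "ranking_z.tsv"))
            link_counts["z_rule_edges"] = len(z_links)
        report["counts"]["linking"] = link_counts
        report["stages"]["link"] = "ok" if link_counts else "skipped"

        # --- networks -----------------------------------------------------
        stage = "network"
        core_set = set(core)
        net_counts: dict = {}
        if z_links is not None or mean_links is not None:
            links = z_links if z_links is not None else mean_links
            bi = build_role_graph([("gene", "tissue", sorted(links.edges))])
            io_formats.write_graph(bi, "graphml", _track(out / "gene_tissue.graphml"))
            io_formats.write_graph(bi, "sif", _track(out / "gene_tissue.sif"))
            net_counts["bipartite_nodes"] = bi.number_of_nodes()
            net_counts["bipartite_edges"] = bi.number_of_edges()
        if assignments:
            cg = [(c, g) for c, g in pairs if g in core_set]
            gg = sorted((g, grp) for g, grp in assignments.items() if g in core_set)
            tri = build_role_graph(
                [("compound", "gene", cg), ("gene", "organ-group", gg)]
            )
            io_formats.write_graph(tri, "graphml", _track(out / "compound_gene_organ.graphml"))
            net_counts["tripartite_nodes"] = tri.number_of_nodes()
            net_counts["tripartite_edges"] = tri.number_of_edges()
        report["counts"]["networks"] = net_counts
        report["stages"]["network"] = "ok" if net_counts else "skipped"

    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineStageError(stage, exc) from exc

    report["config"] = dataclasses.asdict(config)
    report_path = out / "report.json"
    with open(report_path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
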