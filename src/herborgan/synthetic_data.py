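"""Seeded generators for every pipeline input class, with planted ground truth.

Each generator is a pure function of its arguments (including the seed) and
returns in-memory objects plus the relevant slice of a :class:`TruthBundle`;
:func:`gen_study` writes a complete file bundle — compound table, association
table, hub-planted PPI edge list, organ catalog with planted enriched and
depleted terms, expression atlases with planted group-specific boosts, a
tissue→group map, a ready-to-run config, and the truth as JSON — sized to a
realistic single-herb study (17 active compounds, a 448-gene target union
from three sources of 207/312/78 distinct genes, 44 plantable network hubs,
a 150-term organ catalog over a 7,000-gene universe, 84- and 54-tissue
atlases with an 8-group regrouping map).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compound_screen import CompoundRecord
from .errors import PipelineUsageError
from .expression_linking import ExpressionAtlas
from .target_aggregate import TargetAssociation

logger = logging.getLogger(__name__)


@dataclass
class TruthBundle:
    """Planted ground truth for one generated input bundle."""

    seed: int
    planted_active_compounds: frozenset[str] = frozenset()
    planted_pass_associations: frozenset[tuple[str, str, str]] = frozenset()
    per_source_counts: dict[str, int] = field(default_factory=dict)
    union_size: int | None = None
    planted_hubs: frozenset[str] = frozenset()
    planted_enriched_terms: dict[str, float] = field(default_factory=dict)
    planted_depleted_terms: tuple[str, ...] = ()
    planted_gene_groups: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["planted_active_compounds"] = sorted(self.planted_active_compounds)
        payload["planted_pass_associations"] = sorted(map(list, self.planted_pass_associations))
        payload["planted_hubs"] = sorted(self.planted_hubs)
        payload["planted_depleted_terms"] = list(self.planted_depleted_terms)
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthBundle":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            seed=payload["seed"],
            planted_active_compounds=frozenset(payload["planted_active_compounds"]),
            planted_pass_associations=frozenset(
                tuple(row) for row in payload["planted_pass_associations"]
            ),
            per_source_counts=payload["per_source_counts"],
            union_size=payload["union_size"],
            planted_hubs=frozenset(payload["planted_hubs"]),
            planted_enriched_terms=payload["planted_enriched_terms"],
            planted_depleted_terms=tuple(payload["planted_depleted_terms"]),
            planted_gene_groups=payload["planted_gene_groups"],
        )


# ---------------------------------------------------------------------------
# compounds


def gen_compounds(
    n: int = 170,
    frac_active: float = 0.1,
    seed: int = 0,
    dup_fraction: float = 0.15,
) -> tuple[list[CompoundRecord], TruthBundle]:
    """Compound records with exactly ``round(n * frac_active)`` planted actives.

    Actives draw OB ~ U(30, 70) and DL ~ U(0.18, 0.9); inactives fail at
    least one bound.  A ``dup_fraction`` of compounds is duplicated under a
    second source label (exact copies), so deduplication does not change the
    active count.
    """
    if not 0 <= frac_active <= 1:
        raise PipelineUsageError("frac_active must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_active = round(n * frac_active)
    records: list[CompoundRecord] = []
    active_names: list[str] = []
    for i in range(n):
        name = f"cmpd{i + 1:04d}"
        cid = 100000 + i
        if i < n_active:
            ob = float(rng.uniform(30.0, 70.0))
            dl = float(rng.uniform(0.18, 0.9))
            active_names.append(name)
        else:
            mode = rng.choice(["ob", "dl", "both"])
            ob = float(rng.uniform(0.0, 29.9)) if mode in ("ob", "both") else float(
                rng.uniform(30.0, 70.0)
            )
            dl = float(rng.uniform(0.0, 0.17)) if mode in ("dl", "both") else float(
                rng.uniform(0.18, 0.9)
            )
        records.append(
            CompoundRecord(name=name, cid=cid, ob=round(ob, 2), dl=round(dl, 3),
                           sources=frozenset({"TCMSP"}))
        )
    n_dup = round(n * dup_fraction)
    dup_idx = rng.choice(n, size=n_dup, replace=False)
    for i in sorted(dup_idx):
        r = records[i]
        records.append(dataclasses.replace(r, sources=frozenset({"HIT2.0"})))
    truth = TruthBundle(seed=seed, planted_active_compounds=frozenset(active_names))
    return records, truth


# ---------------------------------------------------------------------------
# associations


def gen_associations(
    n_rows: int = 200,
    compounds: list[str] | None = None,
    genes: list[str] | None = None,
    seed: int = 0,
) -> tuple[list[TargetAssociation], TruthBundle]:
    """Mixed-source association rows with planted pass/fail confidence labels.

    Sources rotate over TCMSP (no rule: always passes), HIT2.0 (letter grades
    A–E; A/B/C pass) and BATMAN-TCM (score U(0, 60); >= 30 passes).
    """
    rng = np.random.default_rng(seed)
    compounds = compounds or [f"cmpd{i + 1:04d}" for i in range(10)]
    genes = genes or [f"GENE{i + 1:05d}" for i in range(80)]
    sources = ("TCMSP", "HIT2.0", "BATMAN-TCM")
    rows: list[TargetAssociation] = []
    passing: set[tuple[str, str, str]] = set()
    for i in range(n_rows):
        source = sources[i % 3]
        compound = str(rng.choice(compounds))
        gene = str(rng.choice(genes))
        level, score = None, None
        ok = True
        if source == "HIT2.0":
            level = str(rng.choice(["A", "B", "C", "D", "E"]))
            ok = level in ("A", "B", "C")
        elif source == "BATMAN-TCM":
            score = float(np.round(rng.uniform(0.0, 60.0), 2))
            ok = score >= 30.0
        rows.append(
            TargetAssociation(
                compound_key=compound, gene=gene, source=source,
                confidence_level=level, score=score,
            )
        )
        if ok:
            passing.add((compound, gene, source))
    truth = TruthBundle(seed=seed, planted_pass_associations=frozenset(passing))
    return rows, truth


# ---------------------------------------------------------------------------
# PPI


def gen_ppi(
    n_genes: int = 200,
    n_hubs: int = 3,
    spoke_p: float = 0.01,
    hub_p: float = 0.8,
    seed: int = 0,
    genes: list[str] | None = None,
    decoy_p: float = 0.02,
    force: bool = False,
) -> tuple[list[tuple[str, str, float]], TruthBundle]:
    """Hub-planted scored edge list.

    Pairs involving a hub are wired with probability ``hub_p`` and spoke–spoke
    pairs with ``spoke_p``; planted edges carry scores in (0.9, 1.0] and decoy
    edges (extra pairs at ``decoy_p``) scores <= 0.9, so a strict 0.9 score
    cutoff keeps exactly the planted wiring.  Scores are multiples of 1/1000
    and survive the 0–1000 integer export scale exactly.  ``hub_p <= spoke_p``
    cannot guarantee hub recovery and is refused unless ``force``.
    """
    if genes is None:
        genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    else:
        n_genes = len(genes)
    if n_hubs >= n_genes:
        raise PipelineUsageError("n_hubs must be smaller than n_genes")
    if hub_p <= spoke_p and not force:
        raise PipelineUsageError(
            "hub_p <= spoke_p cannot guarantee hub recovery; pass force=True to override"
        )
    rng = np.random.default_rng(seed)
    hub_idx = set(map(int, rng.choice(n_genes, size=n_hubs, replace=False)))
    iu, ju = np.triu_indices(n_genes, k=1)
    is_hub_pair = np.isin(iu, list(hub_idx)) | np.isin(ju, list(hub_idx))
    p = np.where(is_hub_pair, hub_p, spoke_p)
    u = rng.random(iu.size)
    planted = u < p
    decoy = (~planted) & (rng.random(iu.size) < decoy_p)
    edges: list[tuple[str, str, float]] = []
    planted_scores = rng.integers(901, 1000, size=int(planted.sum())) / 1000.0
    decoy_scores = rng.integers(300, 901, size=int(decoy.sum())) / 1000.0
    for (i, j), s in zip(zip(iu[planted], ju[planted]), planted_scores):
        edges.append((genes[i], genes[j], float(s)))
    for (i, j), s in zip(zip(iu[decoy], ju[decoy]), decoy_scores):
        edges.append((genes[i], genes[j], float(s)))
    truth = TruthBundle(seed=seed, planted_hubs=frozenset(genes[i] for i in hub_idx))
    return edges, truth


# ---------------------------------------------------------------------------
# catalog + gene list


def _universe(universe_size: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(universe_size)]


def gen_catalog_and_list(
    n_terms: int = 150,
    universe_size: int = 7000,
    planted_term_size: int = 100,
    list_size: int = 50,
    signal_fraction: float | None = 0.6,
    depleted_term_size: int = 1500,
    term_size_range: tuple[int, int] = (100, 2000),
    seed: int = 0,
):
    """Organ catalog with one planted enriched and one planted depleted term.

    The query list draws each gene from the planted term with probability
    ``signal_fraction`` and otherwise uniformly from the remaining universe
    (always avoiding the depleted term, which the list must miss entirely).
    ``signal_fraction=None`` draws the list uniformly from the whole universe
    (the null condition for calibration; no terms are avoided).  Non-planted
    term sizes draw from ``term_size_range``, matching the ~150,000
    associations a 150-term organ catalog carries over a ~7,000-gene universe.

    Returns ``(catalog, gene_list, truth)``.
    """
    from .io_formats import Catalog

    if planted_term_size > universe_size:
        raise PipelineUsageError("planted_term_size must not exceed universe_size")
    rng = np.random.default_rng(seed)
    universe = _universe(universe_size)
    uni_arr = np.array(universe)
    enriched = frozenset(rng.choice(uni_arr, size=planted_term_size, replace=False))
    depleted_pool = np.array(sorted(set(universe) - enriched))
    depleted = frozenset(rng.choice(depleted_pool, size=depleted_term_size, replace=False))
    terms: dict[str, frozenset[str]] = {
        "planted_enriched": enriched,
        "planted_depleted": depleted,
    }
    sizes = rng.integers(term_size_range[0], term_size_range[1] + 1, size=n_terms - 2)
    for t, size in enumerate(sizes):
        terms[f"organ{t + 1:03d}"] = frozenset(
            rng.choice(uni_arr, size=int(size), replace=False)
        )
    if signal_fraction is None:
        gene_list = list(map(str, rng.choice(uni_arr, size=list_size, replace=False)))
        effect: dict[str, float] = {}
        dep_terms: tuple[str, ...] = ()
    else:
        n_signal = int(rng.binomial(list_size, signal_fraction))
        n_signal = min(n_signal, planted_term_size)
        signal = rng.choice(np.array(sorted(enriched)), size=n_signal, replace=False)
        rest_pool = np.array(sorted(set(universe) - enriched - depleted))
        rest = rng.choice(rest_pool, size=list_size - n_signal, replace=False)
        gene_list = list(map(str, np.concatenate([signal, rest])))
        effect = {"planted_enriched": float(signal_fraction)}
        dep_terms = ("planted_depleted",)
    catalog = Catalog(terms=terms, universe=frozenset(universe))
    truth = TruthBundle(
        seed=seed, planted_enriched_terms=effect, planted_depleted_terms=dep_terms
    )
    return catalog, gene_list, truth


# ---------------------------------------------------------------------------
# expression atlases


def gen_atlas(
    n_genes: int = 200,
    tissues: list[str] | None = None,
    grouping: dict[str, str] | None = None,
    fold: float = 4.0,
    cv: float = 0.3,
    seed: int = 0,
    genes: list[str] | None = None,
    planted_groups: dict[str, str] | None = None,
    n_atlases: int = 2,
    base_mean: float = 100.0,
) -> tuple[list[ExpressionAtlas], TruthBundle]:
    """Expression atlases with a planted per-gene organ-group boost.

    Each cell draws lognormal noise around a per-gene baseline (coefficient of
    variation ``cv``); the tissues of a gene's planted group are multiplied by
    ``fold``.  ``n_atlases`` independently re-noised copies share the same
    planted truth (for consensus tests).  ``fold = 1`` yields the no-signal
    (chance-level) condition.
    """
    if fold < 1:
        raise PipelineUsageError("fold must be >= 1")
    from .expression_linking import default_organ_grouping

    grouping = grouping if grouping is not None else default_organ_grouping()
    tissues = tissues if tissues is not None else sorted(grouping)
    if genes is None:
        genes = [f"G{i + 1:04d}" for i in range(n_genes)]
    rng = np.random.default_rng(seed)
    groups = sorted({grouping[t] for t in tissues if t in grouping})
    if not groups:
        raise PipelineUsageError("grouping covers none of the requested tissues")
    if planted_groups is None:
        planted_groups = {g: str(rng.choice(groups)) for g in genes}
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    meanlog = np.log(base_mean) + rng.normal(0.0, 0.5, size=len(genes))
    boost = np.ones((len(genes), len(tissues)))
    for gi, gene in enumerate(genes):
        grp = planted_groups[gene]
        for ti, t in enumerate(tissues):
            if grouping.get(t) == grp:
                boost[gi, ti] = fold
    atlases: list[ExpressionAtlas] = []
    for _ in range(n_atlases):
        noise = rng.lognormal(mean=0.0, sigma=sigma, size=(len(genes), len(tissues)))
        values = np.exp(meanlog)[:, None] * boost * noise
        frame = pd.DataFrame(np.round(values, 4), index=genes, columns=tissues)
        atlases.append(ExpressionAtlas(frame))
    truth = TruthBundle(seed=seed, planted_gene_groups=dict(planted_groups))
    return atlases, truth


# ---------------------------------------------------------------------------
# full study bundle


def gen_study(seed: int = 0, out_dir: str | Path = "study") -> tuple[dict[str, Path], TruthBundle]:
    """Write a complete, internally consistent input bundle plus its truth.

    The planted magnitudes mirror a realistic single-herb study: 170 compound
    rows of which 17 pass the ADME screen; three association sources with
    207, 312 and 78 distinct passing genes forming a 448-gene union; a PPI
    edge list over the union with 44 planted hubs; a 150-term catalog over a
    7,000-gene universe with planted enriched and depleted organ terms; an
    84-tissue atlas for above-mean linking and a 54-tissue re-noised pair for
    consensus Z-score linking, all sharing one planted gene→group map.
    """
    from . import io_formats
    from .expression_linking import default_organ_grouping
    from .network_pipeline import RunConfig

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(seed)
    child = lambda: int(root.integers(0, 2**31 - 1))  # noqa: E731

    # compounds ------------------------------------------------------------
    records, c_truth = gen_compounds(n=170, frac_active=0.1, seed=child())
    compounds_path = out / "compounds.tsv"
    io_formats.write_compound_table(records, compounds_path)
    actives = sorted(c_truth.planted_active_compounds)

    # associations ---------------------------------------------------------
    rng = np.random.default_rng(child())
    universe = _universe(7000)
    union = sorted(map(str, rng.choice(np.array(universe), size=448, replace=False)))
    tcmsp_genes = set(map(str, rng.choice(np.array(union), size=207, replace=False)))
    remaining = sorted(set(union) - tcmsp_genes)  # 241 genes must come from HIT2.0
    hit_genes = set(remaining) | set(
        map(str, rng.choice(np.array(sorted(tcmsp_genes)), size=312 - len(remaining), replace=False))
    )
    batman_genes = set(map(str, rng.choice(np.array(union), size=78, replace=False)))
    assoc_rows: list[TargetAssociation] = []
    passing: set[tuple[str, str, str]] = set()

    def _emit(source: str, genes: set[str]) -> None:
        for gene in sorted(genes):
            compound = str(rng.choice(actives))
            level = score = None
            if source == "HIT2.0":
                level = str(rng.choice(["A", "B", "C"]))
            elif source == "BATMAN-TCM":
                score = float(np.round(rng.uniform(30.0, 60.0), 2))
            assoc_rows.append(
                TargetAssociation(
                    compound_key=compound, gene=gene, source=source,
                    confidence_level=level, score=score,
                )
            )
            passing.add((compound, gene, source))

    _emit("TCMSP", tcmsp_genes)
    _emit("HIT2.0", hit_genes)
    _emit("BATMAN-TCM", batman_genes)
    decoys = [f"DECOY{i + 1:04d}" for i in range(60)]
    for i, gene in enumerate(decoys):
        if i % 3 == 0:
            assoc_rows.append(
                TargetAssociation(
                    compound_key=str(rng.choice(actives)), gene=gene, source="HIT2.0",
                    confidence_level=str(rng.choice(["D", "E"])),
                )
            )
        else:
            assoc_rows.append(
                TargetAssociation(
                    compound_key=str(rng.choice(actives)), gene=gene, source="BATMAN-TCM",
                    score=float(np.round(rng.uniform(0.0, 29.9), 2)),
                )
            )
    assoc_path = out / "associations.tsv"
    io_formats.write_association_table(assoc_rows, assoc_path)

    # PPI ------------------------------------------------------------------
    edges, p_truth = gen_ppi(genes=union, n_hubs=44, hub_p=0.8, spoke_p=0.01, seed=child())
    ppi_path = out / "ppi.tsv"
    io_formats.write_edge_list(edges, ppi_path, scale=1000)

    # catalog --------------------------------------------------------------
    cat_rng = np.random.default_rng(child())
    uni_arr = np.array(universe)
    union_set = set(union)
    in_union = np.array(union)
    off_union = np.array(sorted(set(universe) - union_set))
    enriched = frozenset(map(str, cat_rng.choice(in_union, size=60, replace=False))) | frozenset(
        map(str, cat_rng.choice(off_union, size=40, replace=False))
    )
    depleted = frozenset(map(str, cat_rng.choice(off_union, size=1500, replace=False)))
    terms: dict[str, frozenset[str]] = {
        "planted_enriched": enriched,
        "planted_depleted": depleted,
    }
    sizes = cat_rng.integers(100, 2001, size=148)
    for t, size in enumerate(sizes):
        terms[f"organ{t + 1:03d}"] = frozenset(
            map(str, cat_rng.choice(uni_arr, size=int(size), replace=False))
        )
    catalog = io_formats.Catalog(terms=terms, universe=frozenset(universe))
    catalog_path = out / "catalog.gmt"
    io_formats.write_catalog_gmt(catalog, catalog_path)

    # atlases --------------------------------------------------------------
    grouping = default_organ_grouping()
    grouped_tissues = sorted(grouping)
    tissues84 = grouped_tissues + [f"tissue{i + 1:02d}" for i in range(84 - len(grouped_tissues))]
    tissues54 = grouped_tissues + [f"tissue{i + 1:02d}" for i in range(54 - len(grouped_tissues))]
    group_rng = np.random.default_rng(child())
    group_names = sorted(set(grouping.values()))
    planted_groups = {g: str(group_rng.choice(group_names)) for g in union}
    (atlas_mean,), _ = gen_atlas(
        genes=union, tissues=tissues84, grouping=grouping, fold=4.0, cv=0.3,
        seed=child(), planted_groups=planted_groups, n_atlases=1,
    )
    (atlas_z_a, atlas_z_b), _ = gen_atlas(
        genes=union, tissues=tissues54, grouping=grouping, fold=4.0, cv=0.3,
        seed=child(), planted_groups=planted_groups, n_atlases=2,
    )
    atlas_mean_path = out / "atlas_mean.tsv"
    atlas_z_a_path = out / "atlas_z_a.tsv"
    atlas_z_b_path = out / "atlas_z_b.tsv"
    io_formats.write_expression_matrix(atlas_mean, atlas_mean_path)
    io_formats.write_expression_matrix(atlas_z_a, atlas_z_a_path)
    io_formats.write_expression_matrix(atlas_z_b, atlas_z_b_path)
    grouping_path = out / "grouping.tsv"
    with open(grouping_path, "w", encoding="utf-8", newline="\n") as fh:
        for t in grouped_tissues:
            fh.write(f"{t}\t{grouping[t]}\n")

    # config + truth -------------------------------------------------------
    config = RunConfig(
        compounds=str(compounds_path),
        associations=str(assoc_path),
        ppi=str(ppi_path),
        catalog=str(catalog_path),
        atlas_mean=str(atlas_mean_path),
        atlas_z_a=str(atlas_z_a_path),
        atlas_z_b=str(atlas_z_b_path),
        grouping=str(grouping_path),
        out_dir=str(out / "results"),
        seed=seed,
    )
    config_path = out / "config.txt"
    config.to_file(config_path)

    truth = TruthBundle(
        seed=seed,
        planted_active_compounds=c_truth.planted_active_compounds,
        planted_pass_associations=frozenset(passing),
        per_source_counts={"TCMSP": 207, "HIT2.0": 312, "BATMAN-TCM": 78},
        union_size=448,
        planted_hubs=p_truth.planted_hubs,
        planted_enriched_terms={"planted_enriched": 60 / 448},
        planted_depleted_terms=("planted_depleted",),
        planted_gene_groups=planted_groups,
    )
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    paths = {
        "compounds": compounds_path,
        "associations": assoc_path,
        "ppi": ppi_path,
        "catalog": catalog_path,
        "atlas_mean": atlas_mean_path,
        "atlas_z_a": atlas_z_a_path,
        "atlas_z_b": atlas_z_b_path,
        "grouping": grouping_path,
        "config": config_path,
        "truth": truth_path,
    }
    return paths, truth
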