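"""Gene–tissue linking from expression atlases.

Two linking rules are implemented, both strict:

* above-mean: a gene links to a tissue where its expression strictly exceeds
  its own cross-tissue mean (microarray-atlas convention);
* positive Z: a gene links to a tissue where its row Z-score is strictly > 0
  (consensus-nTPM convention).

The two rules are mathematically identical on non-constant rows
(z > 0  <=>  x > row mean); both are kept because they are the interfaces the
two atlas dialects expose.  A consensus of two atlases takes the per-cell
maximum (the nTPM convention), and each gene can finally be assigned to the
organ group where its expression is highest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DomainError, PipelineUsageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExpressionAtlas:
    """A non-negative gene × tissue expression matrix.

    ``frame`` holds genes on the index and tissues on the columns; units are
    whatever the source reports (arbitrary intensity, TPM or nTPM).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        if f.index.has_duplicates:
            raise DomainError("duplicate gene names in atlas")
        if f.columns.has_duplicates:
            raise DomainError("duplicate tissue names in atlas")
        if (f.to_numpy() < 0).any():
            raise DomainError("atlas contains negative expression values")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def tissues(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy()


@dataclass(frozen=True)
class ZMatrix:
    """Row-standardized expression; constant rows are flagged, not divided."""

    frame: pd.DataFrame
    constant_rows: frozenset[str]
    ddof: int = 1


@dataclass(frozen=True)
class LinkSet:
    """Bipartite gene–tissue edges produced by one linking rule."""

    edges: frozenset[tuple[str, str]]
    rule: str

    def __len__(self) -> int:
        return len(self.edges)


def consensus_max(atlas_a: ExpressionAtlas, atlas_b: ExpressionAtlas) -> ExpressionAtlas:
    """Per-cell maximum over two sources (the consensus-nTPM convention).

    Genes: intersection of the two sources (a consensus is undefined for a
    gene absent from one of them), in ``atlas_a`` order.  Tissues: union, with
    ``atlas_a``'s order first; for a tissue present in only one source that
    source's value is carried.
    """
    genes = [g for g in atlas_a.genes if g in set(atlas_b.genes)]
    tissues = list(atlas_a.tissues) + [t for t in atlas_b.tissues if t not in set(atlas_a.tissues)]
    a = atlas_a.frame.reindex(index=genes, columns=tissues)
    b = atlas_b.frame.reindex(index=genes, columns=tissues)
    # take a where a >= b or b is missing, else b; a tissue absent from one
    # source keeps the other source's value
    merged = a.where(a.ge(b) | b.isna(), b)
    return ExpressionAtlas(merged)


def link_above_mean(atlas: ExpressionAtlas) -> LinkSet:
    """Link (gene, tissue) where expression strictly exceeds the gene's mean.

    Constant rows produce no links (no value exceeds the common mean).
    """
    f = atlas.frame
    mask = f.gt(f.mean(axis=1), axis=0)
    edges = frozenset((g, t) for (g, t) in mask.stack()[mask.stack()].index)
    return LinkSet(edges=edges, rule="above_mean")


def zscore_rows(atlas: ExpressionAtlas, ddof: int = 1) -> ZMatrix:
    """Row-wise Z-scores: (x − row mean) / row sd with the given ``ddof``.

    Rows with zero standard deviation are flagged in ``constant_rows`` and
    left as NaN rather than divided.
    """
    if len(atlas.tissues) < 2:
        raise PipelineUsageError("Z-scores need at least two tissues")
    f = atlas.frame
    mu = f.mean(axis=1)
    sd = f.std(axis=1, ddof=ddof)
    constant = sd.index[(sd == 0) | sd.isna()]
    z = f.sub(mu, axis=0).div(sd.where(sd > 0), axis=0)
    return ZMatrix(frame=z, constant_rows=frozenset(constant), ddof=ddof)


def link_positive_z(z: ZMatrix) -> LinkSet:
    """Link (gene, tissue) where the Z-score is strictly positive."""
    f = z.frame.drop(index=list(z.constant_rows), errors="ignore")
    mask = f.gt(0)
    edges = frozenset((g, t) for (g, t) in mask.stack()[mask.stack()].index)
    return LinkSet(edges=edges, rule="z_positive")


def assign_top_group(
    atlas: ExpressionAtlas, grouping: Mapping[str, str]
) -> dict[str, str]:
    """Assign each gene to the organ group with its highest expression.

    A group's value for a gene is the maximum over its member tissues; the
    gene goes to the argmax group.  Tissues absent from ``grouping`` are
    ignored.  Ties go to the lexicographically smallest group name (counted
    and logged); genes with all-zero expression across grouped tissues are
    left unassigned (counted and logged).
    """
    grouped_tissues = [t for t in atlas.tissues if t in grouping]
    if not grouped_tissues:
        raise PipelineUsageError("grouping covers none of the atlas tissues")
    sub = atlas.frame[grouped_tissues]
    group_of = {t: grouping[t] for t in grouped_tissues}
    group_max = sub.T.groupby(group_of).max().T  # genes x groups
    out: dict[str, str] = {}
    ties = 0
    unassigned = 0
    arr = group_max.to_numpy()
    groups = np.asarray(group_max.columns)
    order = np.argsort(groups)  # lexicographic tie-break via first argmax on sorted cols
    arr = arr[:, order]
    groups = groups[order]
    for i, gene in enumerate(group_max.index):
        row = arr[i]
        if np.all(row == 0):
            unassigned += 1
            continue
        best = int(np.argmax(row))
        if np.sum(row == row[best]) > 1:
            ties += 1
        out[gene] = str(groups[best])
    if ties:
        logger.info("assign_top_group: %d tie(s) broken lexicographically", ties)
    if unassigned:
        logger.info("assign_top_group: %d gene(s) all-zero across grouped tissues", unassigned)
    return out


def organ_degree_ranking(links: LinkSet | Iterable[tuple[str, str]]) -> list[tuple[str, int]]:
    """Tissues ranked by the number of genes linked to them (desc, then name)."""
    edges = links.edges if isinstance(links, LinkSet) else set(links)
    counts: dict[str, int] = {}
    for _, tissue in edges:
        counts[tissue] = counts.get(tissue, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def default_organ_grouping() -> dict[str, str]:
    """The bundled 15-tissue → 8-organ-group regrouping map.

    Groups hematopoietic cell types by their organ of origin (myeloid and
    stem-cell compartments → bone marrow; circulating monocytes/NK/whole
    blood → whole blood; dendritic/B/T cell types → lymphoid tissue) and
    keeps solid tissues as their own groups.
    """
    from .io_formats import read_grouping, _data_path

    return read_grouping(_data_path("organ_grouping.tsv"))
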