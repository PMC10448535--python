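"""Per-source confidence filtering of compound→gene associations and target union.

Target databases ship associations with heterogeneous confidence annotations:
curated sources grade links with letters (A best), similarity-based predictors
attach a numeric score.  The rules here keep letter grades A/B/C and numeric
scores >= 30 (both inclusive), pass sources without a stated rule unchanged,
and form the deduplicated, sorted gene union used downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

from .errors import DomainError

logger = logging.getLogger(__name__)

DEFAULT_LEVELS = frozenset({"A", "B", "C"})
DEFAULT_SCORE_CUTOFF = 30.0

#: Source labels subject to the letter-grade rule / the numeric-score rule.
_LEVEL_SOURCES = {"HIT2", "HIT2.0", "HIT"}
_SCORE_SOURCES = {"BATMAN", "BATMAN-TCM"}


@dataclass(frozen=True)
class TargetAssociation:
    """One compound→gene link as asserted by one source database."""

    compound_key: str
    gene: str
    source: str
    confidence_level: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise DomainError("gene symbol must be non-empty")
        if self.score is not None and self.score < 0:
            raise DomainError(f"score must be >= 0, got {self.score}")


def _rule_for(source: str) -> str:
    up = source.strip().upper()
    if up in _LEVEL_SOURCES:
        return "level"
    if up in _SCORE_SOURCES:
        return "score"
    return "none"


def filter_associations(
    assocs: list[TargetAssociation],
    allowed_levels: frozenset[str] = DEFAULT_LEVELS,
    score_cutoff: float = DEFAULT_SCORE_CUTOFF,
) -> list[TargetAssociation]:
    """Apply the per-source confidence rules.

    Letter-graded rows are kept iff their grade is in ``allowed_levels``;
    score-based rows iff score >= ``score_cutoff`` (inclusive); rows from
    sources without a stated rule pass unchanged.  Graded-source rows missing
    their grade, and score-source rows missing their score, are excluded and
    logged.
    """
    kept: list[TargetAssociation] = []
    missing = 0
    allowed = {lv.upper() for lv in allowed_levels}
    for a in assocs:
        rule = _rule_for(a.source)
        if rule == "level":
            if a.confidence_level is None:
                missing += 1
                continue
            if a.confidence_level.strip().upper() in allowed:
                kept.append(a)
        elif rule == "score":
            if a.score is None:
                missing += 1
                continue
            if a.score >= score_cutoff:
                kept.append(a)
        else:
            kept.append(a)
    if missing:
        logger.info(
            "filter_associations: excluded %d row(s) missing their confidence field",
            missing,
        )
    return kept


@dataclass(frozen=True)
class TargetUnion:
    """Deduplicated gene union plus the per-source bookkeeping for run reports."""

    genes: tuple[str, ...]
    per_source: dict[str, int]
    pairwise_overlap: dict[tuple[str, str], int]

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


def union_targets(assocs: list[TargetAssociation]) -> TargetUnion:
    """Distinct gene symbols (sorted), with per-source and overlap counts.

    Expects confidence-filtered input.  ``per_source`` counts distinct genes
    per source; ``pairwise_overlap`` counts the gene-set intersections between
    each pair of sources.
    """
    by_source: dict[str, set[str]] = {}
    for a in assocs:
        by_source.setdefault(a.source, set()).add(a.gene)
    all_genes: set[str] = set().union(*by_source.values()) if by_source else set()
    overlaps = {
        (s1, s2): len(by_source[s1] & by_source[s2])
        for s1, s2 in combinations(sorted(by_source), 2)
    }
    return TargetUnion(
        genes=tuple(sorted(all_genes)),
        per_source={s: len(g) for s, g in sorted(by_source.items())},
        pairwise_overlap=overlaps,
    )


def compound_target_map(
    assocs: list[TargetAssociation],
) -> list[tuple[str, str]]:
    """Distinct (compound, gene) pairs for bipartite network building.

    Multiple sources asserting the same pair collapse to one edge.  The pairs
    are sorted for determinism.  Compounds appearing in the input with zero
    surviving targets simply contribute no pairs; callers that want them as
    isolated nodes keep their own compound list.
    """
    return sorted({(a.compound_key, a.gene) for a in assocs})
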