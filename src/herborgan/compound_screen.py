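"""Compound deduplication and ADME activity screening.

Herbal compound tables come from several databases that overlap and use
inconsistent identifiers.  This module merges records that share any strong
identifier (PubChem CID, InChIKey, CAS number, or a normalized name) and then
applies the standard oral-bioavailability / drug-likeness activity filter
(OB >= 30 %, DL >= 0.18, both inclusive).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .errors import DomainError

logger = logging.getLogger(__name__)

#: Greek letters commonly appearing in compound names, normalized to Latin
#: spellings so that e.g. "β-ecdysterone" and "Β-ecdysterone" compare equal.
_GREEK = {
    "α": "alpha", "β": "beta", "γ": "gamma", "δ": "delta", "ε": "epsilon",
    "κ": "kappa", "λ": "lambda", "μ": "mu", "ω": "omega",
    "Α": "alpha", "Β": "beta", "Γ": "gamma", "Δ": "delta", "Ε": "epsilon",
    "Κ": "kappa", "Λ": "lambda", "Μ": "mu", "Ω": "omega",
}

_WS = re.compile(r"\s+")


def normalize_name(name: str) -> str:
    """Case-fold, collapse whitespace and spell out Greek letters."""
    out = "".join(_GREEK.get(ch, ch) for ch in name)
    return _WS.sub(" ", out.strip()).casefold()


@dataclass(frozen=True)
class CompoundRecord:
    """One herb compound with its identifiers and ADME scores.

    Parameters
    ----------
    name : str
        Compound name as given by the source database.
    cid : int, optional
        PubChem compound identifier.
    cas : str, optional
        CAS registry number.
    inchikey : str, optional
        InChIKey string.
    ob : float, optional
        Oral bioavailability in percent (>= 0).
    dl : float, optional
        Drug-likeness score in [0, 1].
    sources : frozenset of str
        Labels of the databases this record came from.
    """

    name: str
    cid: int | None = None
    cas: str | None = None
    inchikey: str | None = None
    ob: float | None = None
    dl: float | None = None
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ob is not None and self.ob < 0:
            raise DomainError(f"OB must be >= 0, got {self.ob} for {self.name!r}")
        if self.dl is not None and not (0.0 <= self.dl <= 1.0):
            raise DomainError(f"DL must lie in [0, 1], got {self.dl} for {self.name!r}")

    def identifier_keys(self) -> list[tuple[str, object]]:
        """Typed identifier keys in merge priority order (cid > inchikey > cas > name)."""
        keys: list[tuple[str, object]] = []
        if self.cid is not None:
            keys.append(("cid", self.cid))
        if self.inchikey:
            keys.append(("inchikey", self.inchikey.strip().upper()))
        if self.cas:
            keys.append(("cas", self.cas.strip()))
        norm = normalize_name(self.name) if self.name else ""
        if norm:
            keys.append(("name", norm))
        return keys


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _merge(records: list[CompoundRecord]) -> CompoundRecord:
    """Merge duplicates: union of sources, max OB/DL, first non-missing identifiers."""
    base = records[0]
    cid = next((r.cid for r in records if r.cid is not None), None)
    cas = next((r.cas for r in records if r.cas), None)
    inchikey = next((r.inchikey for r in records if r.inchikey), None)
    obs = [r.ob for r in records if r.ob is not None]
    dls = [r.dl for r in records if r.dl is not None]
    sources: frozenset[str] = frozenset().union(*(r.sources for r in records))
    return replace(
        base,
        cid=cid,
        cas=cas,
        inchikey=inchikey,
        ob=max(obs) if obs else None,
        dl=max(dls) if dls else None,
        sources=sources,
    )


def dedup_compounds(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Merge records sharing any identifier; drop records with none at all.

    Merging is transitive (union-find over shared identifier keys).  A merged
    record keeps the union of source labels and the maximum OB/DL where the
    sources disagree.  Records with no CID, InChIKey, CAS, or usable name are
    dropped; the drop count is logged, not raised.
    """
    uf = _UnionFind(len(records))
    seen: dict[tuple[str, object], int] = {}
    keep: list[int] = []
    dropped = 0
    for i, rec in enumerate(records):
        keys = rec.identifier_keys()
        if not keys:
            dropped += 1
            continue
        keep.append(i)
        for key in keys:
            if key in seen:
                uf.union(seen[key], i)
            else:
                seen[key] = i
    if dropped:
        logger.info("dedup_compounds: dropped %d record(s) with no identifier", dropped)
    groups: dict[int, list[CompoundRecord]] = {}
    order: list[int] = []
    for i in keep:
        root = uf.find(i)
        if root not in groups:
            groups[root] = []
            order.append(root)
        groups[root].append(records[i])
    return [_merge(groups[root]) for root in order]


def adme_filter(
    records: list[CompoundRecord], ob_min: float = 30.0, dl_min: float = 0.18
) -> list[CompoundRecord]:
    """Keep records with OB >= ``ob_min`` and DL >= ``dl_min`` (inclusive).

    Records missing either score are excluded and counted in the log; input
    order is preserved.
    """
    kept: list[CompoundRecord] = []
    missing = 0
    for rec in records:
        if rec.ob is None or rec.dl is None:
            missing += 1
            continue
        if rec.ob >= ob_min and rec.dl >= dl_min:
            kept.append(rec)
    if missing:
        logger.info("adme_filter: excluded %d record(s) missing OB or DL", missing)
    return kept


def cross_source_overlap(records: list[CompoundRecord]) -> list[CompoundRecord]:
    """Records reported by at least two source databases, sorted by name.

    Expects already-deduplicated input (each compound one record with its
    merged ``sources`` set).
    """
    return sorted((r for r in records if len(r.sources) >= 2), key=lambda r: r.name)
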