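"""Readers and writers for every external file the pipeline touches.

Formats: TSV compound tables, association tables, STRING-dialect edge lists
(0–1000 or 0–1 score scale, auto-detected), GMT or two-column gene→term
catalogs, gene × tissue expression matrices, and graph export to GraphML,
SIF or edge TSV.  All writers emit UTF-8 with LF line endings; every reader
is total on its writer's output.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .compound_screen import CompoundRecord
from .errors import FormatError, PipelineUsageError
from .expression_linking import ExpressionAtlas
from .target_aggregate import TargetAssociation

logger = logging.getLogger(__name__)

_NA_TOKENS = ("NA", "na", "NaN", "nan", "null", "N/A")


@dataclass(frozen=True)
class TableDialect:
    """Delimiter/header/NA conventions for tabular inputs.

    An empty cell is always NA regardless of ``na_tokens``.
    """

    delimiter: str = "\t"
    header: bool = True
    comment_prefix: str = "#"
    na_tokens: tuple[str, ...] = _NA_TOKENS

    def __post_init__(self) -> None:
        if len(self.delimiter) != 1:
            raise FormatError("dialect delimiter must be a single character")
        if "" in self.na_tokens:
            raise FormatError("empty string is implicitly NA; do not list it")


DEFAULT_DIALECT = TableDialect()


@dataclass(frozen=True)
class Catalog:
    """A gene→term annotation catalog (e.g. gene–organ associations).

    ``universe`` defaults to the union of all term gene sets and must contain
    every annotated gene.
    """

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    format: str = "gmt"

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            if not genes:
                raise FormatError(f"catalog term {term!r} has no genes")
            if not genes <= self.universe:
                raise FormatError(f"term {term!r} contains genes outside the universe")

    @property
    def term_count(self) -> int:
        return len(self.terms)


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("herborgan.data") / name)


def _read_table(path: str | Path, dialect: TableDialect) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=dialect.delimiter,
        header=0 if dialect.header else None,
        comment=dialect.comment_prefix or None,
        na_values=[*dialect.na_tokens, ""],  # empty cell is always NA
        keep_default_na=False,
        dtype=str,
        skip_blank_lines=True,
    )


# ---------------------------------------------------------------------------
# compound tables

#: source-specific identifier columns; a non-missing value places the record
#: in that source.
_SOURCE_ID_COLUMNS = {"tcmsp_id": "TCMSP", "hit2_id": "HIT2.0", "batman_id": "BATMAN"}
_CID_ALIASES = ("cid", "pubchem_cid", "pubchem_id")


def read_compound_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[CompoundRecord]:
    """Read one compound record per data row.

    The header must name a ``name`` column, at least one identifier column
    (CID/CAS/InChIKey), ``ob`` and ``dl``, and a source label — either a
    ``source`` column or per-source identifier columns (``tcmsp_id`` …).
    OB/DL are parsed as numbers; missing identifiers stay absent.
    """
    df = _read_table(path, dialect)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("name", "ob", "dl"):
        if required not in cols:
            raise FormatError(f"compound table {path}: missing mandatory column {required!r}")
    cid_col = next((cols[a] for a in _CID_ALIASES if a in cols), None)
    if cid_col is None and "cas" not in cols and "inchikey" not in cols:
        raise FormatError(
            f"compound table {path}: needs at least one identifier column (cid/cas/inchikey)"
        )
    has_source = "source" in cols
    source_id_cols = {cols[c]: label for c, label in _SOURCE_ID_COLUMNS.items() if c in cols}
    if not has_source and not source_id_cols:
        raise FormatError(f"compound table {path}: missing a source label column")

    records: list[CompoundRecord] = []
    for idx, row in df.iterrows():
        line_no = idx + 2 if dialect.header else idx + 1

        def _num(col_key: str) -> float | None:
            raw = row[cols[col_key]]
            if pd.isna(raw) or raw == "":
                return None
            try:
                return float(raw)
            except ValueError:
                raise FormatError(
                    f"compound table {path}, line {line_no}: non-numeric {col_key.upper()} {raw!r}"
                ) from None

        sources: set[str] = set()
        if has_source:
            raw_src = row[cols["source"]]
            if not pd.isna(raw_src) and raw_src:
                sources.add(str(raw_src).strip())
        for col, label in source_id_cols.items():
            if not pd.isna(row[col]) and str(row[col]).strip():
                sources.add(label)
        cid_raw = row[cid_col] if cid_col else None
        records.append(
            CompoundRecord(
                name=str(row[cols["name"]]).strip(),
                cid=int(float(cid_raw)) if cid_raw is not None and not pd.isna(cid_raw) else None,
                cas=(str(row[cols["cas"]]).strip() or None)
                if "cas" in cols and not pd.isna(row[cols["cas"]])
                else None,
                inchikey=(str(row[cols["inchikey"]]).strip() or None)
                if "inchikey" in cols and not pd.isna(row[cols["inchikey"]])
                else None,
                ob=_num("ob"),
                dl=_num("dl"),
                sources=frozenset(sources),
            )
        )
    return records


def write_compound_table(records: Sequence[CompoundRecord], path: str | Path) -> None:
    rows = [
        {
            "name": r.name,
            "cid": r.cid if r.cid is not None else "",
            "cas": r.cas or "",
            "inchikey": r.inchikey or "",
            "ob": r.ob if r.ob is not None else "",
            "dl": r.dl if r.dl is not None else "",
            "source": ";".join(sorted(r.sources)),
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["name", "cid", "cas", "inchikey", "ob", "dl", "source"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def bundled_compound_table() -> list[CompoundRecord]:
    """The bundled 17-row active-compound table (printed OB/DL values)."""
    return read_compound_table(_data_path("rab_active_compounds.tsv"))


# ---------------------------------------------------------------------------
# association tables


def read_association_table(
    path: str | Path, dialect: TableDialect = DEFAULT_DIALECT
) -> list[TargetAssociation]:
    """Read compound→gene association rows: compound, gene, source[, level, score]."""
    df = _read_table(path, dialect)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("compound", "gene", "source"):
        if required not in cols:
            raise FormatError(f"association table {path}: missing mandatory column {required!r}")
    out: list[TargetAssociation] = []
    for idx, row in df.iterrows():
        score_raw = row[cols["score"]] if "score" in cols else None
        if score_raw is not None and not pd.isna(score_raw) and str(score_raw).strip():
            try:
                score = float(score_raw)
            except ValueError:
                raise FormatError(
                    f"association table {path}, line {idx + 2}: non-numeric score {score_raw!r}"
                ) from None
        else:
            score = None
        level_raw = row[cols["level"]] if "level" in cols else None
        level = (
            str(level_raw).strip()
            if level_raw is not None and not pd.isna(level_raw) and str(level_raw).strip()
            else None
        )
        out.append(
            TargetAssociation(
                compound_key=str(row[cols["compound"]]).strip(),
                gene=str(row[cols["gene"]]).strip(),
                source=str(row[cols["source"]]).strip(),
                confidence_level=level,
                score=score,
            )
        )
    return out


def write_association_table(assocs: Sequence[TargetAssociation], path: str | Path) -> None:
    rows = [
        {
            "compound": a.compound_key,
            "gene": a.gene,
            "source": a.source,
            "level": a.confidence_level or "",
            "score": a.score if a.score is not None else "",
        }
        for a in assocs
    ]
    pd.DataFrame(rows, columns=["compound", "gene", "source", "level", "score"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path: str | Path) -> list[tuple[str, str, float]]:
    """Read a STRING-dialect scored edge list: node1 node2 combined_score.

    Whitespace- or tab-delimited.  Scores are normalized to the 0–1 scale:
    any score > 1 marks the whole file as 0–1000 (scores then divided by
    1000); a file mixing integer-scale scores with 0–1 decimals is a format
    error.  Self-loops are dropped with a logged count.  A first line whose
    third field is non-numeric is treated as a header.
    """
    raw: list[tuple[str, str, float]] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise FormatError(f"edge list {path}, line {line_no}: expected 3 fields")
            try:
                score = float(fields[2])
            except ValueError:
                if line_no == 1:
                    continue  # header
                raise FormatError(
                    f"edge list {path}, line {line_no}: non-numeric score {fields[2]!r}"
                ) from None
            raw.append((fields[0], fields[1], score))
    scores = [s for _, _, s in raw]
    if any(s > 1 for s in scores):
        if any(0 < s < 1 for s in scores):
            raise FormatError(f"edge list {path}: mixed 0–1 and 0–1000 score scales")
        raw = [(a, b, s / 1000.0) for a, b, s in raw]
    self_loops = sum(1 for a, b, _ in raw if a == b)
    if self_loops:
        logger.info("read_edge_list: dropped %d self-loop(s)", self_loops)
    return [(a, b, s) for a, b, s in raw if a != b]


def write_edge_list(
    pairs: Iterable[tuple[str, str, float]], path: str | Path, scale: int = 1000
) -> None:
    """Write a STRING-dialect edge list on the 0–1000 (default) or 0–1 scale."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in pairs:
            if scale == 1000:
                fh.write(f"{a}\t{b}\t{round(s * 1000)}\n")
            else:
                fh.write(f"{a}\t{b}\t{s:.6g}\n")


# ---------------------------------------------------------------------------
# catalogs


def read_catalog(
    path: str | Path,
    fmt: str | None = None,
    universe_path: str | Path | None = None,
) -> Catalog:
    """Read a gene→term catalog from GMT or two-column (gene TAB term) TSV.

    Format is auto-detected (``.gmt`` extension, otherwise field count) unless
    ``fmt`` is given.  Duplicate (gene, term) pairs collapse.  The universe is
    the union of all term gene sets unless ``universe_path`` (one gene per
    line) is given, which must be a superset.
    """
    path = Path(path)
    lines: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            lines.append(line.split("\t"))
    if fmt is None:
        if path.suffix.lower() == ".gmt":
            fmt = "gmt"
        else:
            fmt = "two_column" if all(len(f) == 2 for f in lines) else "gmt"
    terms: dict[str, set[str]] = {}
    if fmt == "gmt":
        for fields in lines:
            if len(fields) < 3:
                raise FormatError(f"catalog {path}: GMT line needs term, description, >=1 gene")
            term = fields[0].strip()
            if not term:
                raise FormatError(f"catalog {path}: empty term name")
            genes = {g.strip() for g in fields[2:] if g.strip()}
            if not genes:
                raise FormatError(f"catalog {path}: term {term!r} has no genes")
            terms.setdefault(term, set()).update(genes)
    elif fmt == "two_column":
        for fields in lines:
            if len(fields) != 2:
                raise FormatError(f"catalog {path}: two-column line with {len(fields)} fields")
            gene, term = fields[0].strip(), fields[1].strip()
            if not term:
                raise FormatError(f"catalog {path}: empty term name")
            if not gene:
                raise FormatError(f"catalog {path}: empty gene symbol")
            terms.setdefault(term, set()).add(gene)
    else:
        raise PipelineUsageError(f"unknown catalog format {fmt!r}")
    union: frozenset[str] = frozenset().union(*terms.values()) if terms else frozenset()
    if universe_path is not None:
        universe = frozenset(read_gene_list(universe_path))
        missing = union - universe
        if missing:
            raise FormatError(
                f"catalog {path}: {len(missing)} annotated gene(s) missing from the universe file"
            )
    else:
        universe = union
    return Catalog(
        terms={t: frozenset(g) for t, g in terms.items()}, universe=universe, format=fmt
    )


def write_catalog_gmt(catalog: Catalog, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for term in catalog.terms:
            genes = "\t".join(sorted(catalog.terms[term]))
            fh.write(f"{term}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path) -> ExpressionAtlas:
    """Read a gene × tissue TSV (first column gene symbols, values >= 0).

    Duplicate gene rows are collapsed by per-tissue maximum; a duplicate
    tissue column or a negative value is a format error.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    tissue_names = header[1:]
    if len(set(tissue_names)) != len(tissue_names):
        dup = sorted({t for t in tissue_names if tissue_names.count(t) > 1})
        raise FormatError(f"expression matrix {path}: duplicate tissue column(s) {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        arr = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"expression matrix {path}: non-numeric value ({exc})") from None
    if (arr < 0).any():
        i, j = next(zip(*((arr < 0).nonzero())))
        raise FormatError(
            f"expression matrix {path}: negative value at gene {df.index[i]!r}, "
            f"tissue {df.columns[j]!r}"
        )
    if df.index.has_duplicates:
        n_dup = int(df.index.duplicated().sum())
        logger.info("read_expression_matrix: collapsed %d duplicate gene row(s) by max", n_dup)
        df = df.groupby(level=0, sort=False).max()
    df.index = df.index.astype(str)
    return ExpressionAtlas(df.astype(float))


def write_expression_matrix(atlas: ExpressionAtlas, path: str | Path) -> None:
    atlas.frame.to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


# ---------------------------------------------------------------------------
# gene lists and grouping maps


def read_gene_list(path: str | Path) -> list[str]:
    """One symbol per line; blank lines and #-comments ignored."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_grouping(path: str | Path) -> dict[str, str]:
    """Two-column TSV: tissue name TAB organ-group name."""
    out: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"grouping file {path}, line {line_no}: expected tissue TAB group")
            out[fields[0].strip()] = fields[1].strip()
    return out


def bundled_core_target_groups() -> dict[str, str]:
    """The bundled 44-core-gene → organ-group assignment (printed result table)."""
    return read_grouping(_data_path("core_target_groups.tsv"))


# ---------------------------------------------------------------------------
# graph export

_GRAPH_FORMATS = ("graphml", "sif", "tsv")


def write_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Export a role-annotated graph to GraphML, SIF, or edge TSV.

    GraphML keeps node ``role`` and ``degree`` attributes; SIF uses the
    interaction word ``links``; edge TSV has header node1/node2/role1/role2.
    """
    fmt = fmt.lower()
    if fmt not in _GRAPH_FORMATS:
        raise PipelineUsageError(f"unsupported graph format {fmt!r}; use one of {_GRAPH_FORMATS}")
    if fmt == "graphml":
        nx.write_graphml(graph, path, encoding="utf-8")
    elif fmt == "sif":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            isolated = [n for n in graph.nodes if graph.degree(n) == 0]
            for a, b in graph.edges:
                fh.write(f"{a}\tlinks\t{b}\n")
            for n in isolated:
                fh.write(f"{n}\n")
    else:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("node1\tnode2\trole1\trole2\n")
            for a, b in graph.edges:
                fh.write(
                    f"{a}\t{b}\t{graph.nodes[a].get('role', '')}\t{graph.nodes[b].get('role', '')}\n"
                )
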