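"""Readers and writers for citation pairs, identifier mappings and annotation tables.

All inputs are delimited text (optionally gzip-compressed, detected from the
``.gz`` suffix by pandas). Every reader returns a :class:`LoadReport` alongside
its payload so that row attrition — which is material at bibliographic scale —
is always auditable.

Supported annotation dialects:

``gene2pubmed``
    Tab-separated with columns ``tax_id``, ``GeneID``, ``PubMed_ID`` (the
    header line may carry a leading ``#``). Articles are PubMed IDs, the
    annotation token is the gene identifier, and rows are filtered to a single
    taxon (human, ``9606``, by default).
``generic``
    Two columns, article identifier then annotation token.
``mesh``
    Three columns: article, descriptor, and a major-topic flag (``Y``/``N``);
    an option restricts the store to major-topic descriptors.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Article identifiers are opaque non-empty tokens (PMID-like); comparison is
#: exact string equality.
ArticleID = str

DIALECTS = ("gene2pubmed", "generic", "mesh")

#: NCBI taxon identifier for Homo sapiens, the default gene-dialect filter.
HUMAN_TAXON = "9606"


class IngestError(ValueError):
    """Fatal ingestion problem: missing file, column or unknown dialect."""


def normalize_pmid(value: str) -> str:
    """PMIDs are kept verbatim apart from surrounding whitespace."""
    return str(value).strip()


def normalize_doi(value: str) -> str:
    """DOIs are case-insensitive; case-fold to prevent silent join misses."""
    return str(value).strip().lower()


@dataclass
class LoadReport:
    """Row attrition for one read: rows seen, kept, and skipped by reason."""

    source: str
    rows_read: int = 0
    rows_kept: int = 0
    skipped: dict[str, int] = field(default_factory=dict)

    @property
    def rows_skipped(self) -> int:
        return sum(self.skipped.values())

    def skip(self, reason: str, n: int = 1) -> None:
        self.skipped[reason] = self.skipped.get(reason, 0) + n

    def log(self) -> None:
        logger.info(
            "%s: read %d rows, kept %d, skipped %d %s",
            self.source,
            self.rows_read,
            self.rows_kept,
            self.rows_skipped,
            dict(self.skipped),
        )

    def as_dict(self) -> dict:
        return {
            "source": self.source,
            "rows_read": self.rows_read,
            "rows_kept": self.rows_kept,
            "rows_skipped": self.rows_skipped,
            "skipped_by_reason": dict(self.skipped),
        }


@dataclass
class AnnotationStore:
    """Mapping from article identifier to its set of annotation tokens.

    Every stored article carries at least one annotation; the vocabulary is
    the union of all per-article sets.
    """

    dataset_name: str
    records: dict[ArticleID, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [a for a, s in self.records.items() if not s]
        if empty:
            raise IngestError(
                f"store {self.dataset_name!r}: articles with zero annotations: "
                f"{empty[:5]}"
            )
        self.records = {a: frozenset(s) for a, s in self.records.items()}

    @property
    def vocabulary(self) -> frozenset[str]:
        vocab: set[str] = set()
        for s in self.records.values():
            vocab |= s
        return frozenset(vocab)

    def __contains__(self, article: ArticleID) -> bool:
        return article in self.records

    def __len__(self) -> int:
        return len(self.records)

    def get(self, article: ArticleID) -> frozenset[str]:
        return self.records.get(article, frozenset())

    def articles(self) -> set[ArticleID]:
        return set(self.records)


@dataclass
class IdMapping:
    """External identifier (DOI-like) to article identifier lookup.

    Keys are case-folded on insert and on lookup; a miss is an explicit
    ``None`` rather than an exception, so callers can count attrition.
    """

    pairs: dict[str, ArticleID] = field(default_factory=dict)

    @classmethod
    def from_items(cls, items: Iterable[tuple[str, ArticleID]]) -> "IdMapping":
        return cls({normalize_doi(k): normalize_pmid(v) for k, v in items})

    def lookup(self, external_id: str) -> ArticleID | None:
        return self.pairs.get(normalize_doi(external_id))

    def __len__(self) -> int:
        return len(self.pairs)


def _read_table(path: str | Path, sep: str | None, comment_header: bool = False) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IngestError(f"input file not found: {path}")
    # sep=None lets pandas sniff the delimiter (CSV and TSV both occur)
    df = pd.read_csv(path, sep=sep if sep else None, dtype=str, engine="python")
    if comment_header and df.columns[0].startswith("#"):
        df = df.rename(columns={df.columns[0]: df.columns[0].lstrip("#")})
    return df


def _require_columns(df: pd.DataFrame, names: Sequence[str], source: str) -> None:
    missing = [n for n in names if n not in df.columns]
    if missing:
        raise IngestError(
            f"{source}: missing column(s) {missing}; available: {list(df.columns)}"
        )


def read_citation_pairs(
    path: str | Path,
    citing_col: str = "citing",
    cited_col: str = "cited",
    sep: str | None = None,
    use_positions: bool = False,
    positions: tuple[int, int] = (0, 1),
) -> tuple[list[tuple[str, str]], LoadReport]:
    """Read ordered (citing, cited) identifier pairs from a delimited file.

    Columns are selected by name; ``use_positions`` selects by index instead,
    for header dialects whose column names vary across releases. Rows with an
    empty cell are skipped and counted.
    """
    df = _read_table(path, sep)
    report = LoadReport(source=str(path))
    if use_positions:
        for idx in positions:
            if idx >= df.shape[1]:
                raise IngestError(
                    f"{path}: positional column {idx} out of range "
                    f"({df.shape[1]} columns)"
                )
        citing_col, cited_col = df.columns[positions[0]], df.columns[positions[1]]
    else:
        _require_columns(df, [citing_col, cited_col], str(path))
    pairs: list[tuple[str, str]] = []
    for citing, cited in zip(df[citing_col], df[cited_col]):
        report.rows_read += 1
        if pd.isna(citing) or pd.isna(cited) or not str(citing).strip() or not str(cited).strip():
            report.skip("empty_cell")
            continue
        pairs.append((str(citing).strip(), str(cited).strip()))
        report.rows_kept += 1
    report.log()
    return pairs, report


def read_id_mapping(
    path: str | Path,
    external_col: str = "DOI",
    article_col: str = "PMID",
    sep: str | None = None,
) -> tuple[IdMapping, LoadReport]:
    """Read an external-ID → article-ID mapping table (EBI PMID–PMCID–DOI dialect)."""
    df = _read_table(path, sep)
    report = LoadReport(source=str(path))
    _require_columns(df, [external_col, article_col], str(path))
    pairs: dict[str, ArticleID] = {}
    for ext, art in zip(df[external_col], df[article_col]):
        report.rows_read += 1
        if pd.isna(ext) or pd.isna(art) or not str(ext).strip() or not str(art).strip():
            report.skip("empty_cell")
            continue
        pairs[normalize_doi(ext)] = normalize_pmid(art)
        report.rows_kept += 1
    report.log()
    return IdMapping(pairs), report


def map_citations(
    pairs: Sequence[tuple[str, str]], mapping: IdMapping
) -> tuple[list[tuple[ArticleID, ArticleID]], LoadReport]:
    """Map DOI-level citation pairs to article-ID pairs.

    A pair is retained only when *both* endpoints map; dropped pairs are
    counted by which endpoint failed.
    """
    report = LoadReport(source="map_citations")
    mapped: list[tuple[ArticleID, ArticleID]] = []
    for citing, cited in pairs:
        report.rows_read += 1
        a, b = mapping.lookup(citing), mapping.lookup(cited)
        if a is None and b is None:
            report.skip("both_unmapped")
        elif a is None:
            report.skip("citing_unmapped")
        elif b is None:
            report.skip("cited_unmapped")
        else:
            mapped.append((a, b))
            report.rows_kept += 1
    report.log()
    return mapped, report


def _rows_to_store(
    rows: Iterable[tuple[str, str]], dataset_name: str, report: LoadReport
) -> AnnotationStore:
    records: dict[str, set[str]] = defaultdict(set)
    for article, annot in rows:
        records[article].add(annot)
    store = AnnotationStore(dataset_name, {a: frozenset(s) for a, s in records.items()})
    report.log()
    return store


def read_annotation_table(
    path: str | Path,
    dialect: str = "generic",
    dataset_name: str | None = None,
    taxon_filter: str | None = HUMAN_TAXON,
    major_topic_only: bool = False,
    sep: str | None = None,
    use_positions: bool = False,
) -> tuple[AnnotationStore, LoadReport]:
    """Read an article→annotation table into an :class:`AnnotationStore`.

    ``taxon_filter`` applies only to the ``gene2pubmed`` dialect (default:
    human); ``major_topic_only`` only to ``mesh``. Duplicate
    (article, annotation) rows collapse into the per-article set.
    """
    if dialect not in DIALECTS:
        raise IngestError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    name = dataset_name or Path(path).stem
    report = LoadReport(source=str(path))

    if dialect == "gene2pubmed":
        df = _read_table(path, sep or "\t", comment_header=True)
        cols = ("tax_id", "GeneID", "PubMed_ID")
        if use_positions:
            cols = tuple(df.columns[:3])  # type: ignore[assignment]
        _require_columns(df, cols, str(path))
        rows = []
        for tax, gene, pmid in zip(df[cols[0]], df[cols[1]], df[cols[2]]):
            report.rows_read += 1
            if pd.isna(tax) or pd.isna(gene) or pd.isna(pmid):
                report.skip("malformed_row")
                continue
            if taxon_filter is not None and str(tax).strip() != str(taxon_filter):
                report.skip("taxon_filtered")
                continue
            rows.append((normalize_pmid(pmid), str(gene).strip()))
            report.rows_kept += 1
        return _rows_to_store(rows, name, report), report

    if dialect == "mesh":
        df = _read_table(path, sep)
        cols = ("article", "annotation", "major_topic")
        if use_positions:
            cols = tuple(df.columns[:3])  # type: ignore[assignment]
        _require_columns(df, cols, str(path))
        rows = []
        for art, annot, major in zip(df[cols[0]], df[cols[1]], df[cols[2]]):
            report.rows_read += 1
            if pd.isna(art) or pd.isna(annot):
                report.skip("malformed_row")
                continue
            if major_topic_only and str(major).strip().upper() not in ("Y", "YES", "1", "TRUE"):
                report.skip("not_major_topic")
                continue
            rows.append((normalize_pmid(art), str(annot).strip()))
            report.rows_kept += 1
        return _rows_to_store(rows, name, report), report

    # generic: first two named (or positional) columns
    df = _read_table(path, sep)
    cols = ("article", "annotation")
    if use_positions or not all(c in df.columns for c in cols):
        cols = tuple(df.columns[:2])  # type: ignore[assignment]
    _require_columns(df, cols, str(path))
    rows = []
    for art, annot in zip(df[cols[0]], df[cols[1]]):
        report.rows_read += 1
        if pd.isna(art) or pd.isna(annot) or not str(art).strip() or not str(annot).strip():
            report.skip("malformed_row")
            continue
        rows.append((normalize_pmid(art), str(annot).strip()))
        report.rows_kept += 1
    return _rows_to_store(rows, name, report), report


def read_gold_standard(
    paths: str | Path | Sequence[str | Path],
    dataset_name: str = "gold",
    sep: str | None = "\t",
) -> tuple[AnnotationStore, LoadReport]:
    """Read one or more gold-standard files of (article, annotation) rows.

    Multiple files (e.g. a training and a testing split) are merged by set
    union per article. Headerless two-column TSV is the expected shape; a
    header row, if present, is detected and skipped. An empty result is fatal.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    report = LoadReport(source=";".join(str(p) for p in paths))
    rows: list[tuple[str, str]] = []
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise IngestError(f"input file not found: {path}")
        try:
            df = pd.read_csv(path, sep=sep if sep else "\t", dtype=str,
                             header=None, engine="python")
        except pd.errors.EmptyDataError as err:
            raise IngestError(f"gold standard {path}: empty file") from err
        start = 0
        if df.shape[0] and str(df.iloc[0, 0]).lower() in ("article", "pmid", "id"):
            start = 1
        for _, row in df.iloc[start:].iterrows():
            report.rows_read += 1
            art, annot = row.iloc[0], row.iloc[1] if df.shape[1] > 1 else None
            if pd.isna(art) or annot is None or pd.isna(annot):
                report.skip("malformed_row")
                continue
            rows.append((normalize_pmid(art), str(annot).strip()))
            report.rows_kept += 1
    if not rows:
        raise IngestError(f"gold standard {report.source}: no usable rows")
    return _rows_to_store(rows, dataset_name, report), report


def summarize_store(store: AnnotationStore) -> tuple[int, int]:
    """Return (number of (article, annotation) pairs, number of distinct articles)."""
    n_pairs = sum(len(s) for s in store.records.values())
    return n_pairs, len(store.records)


def write_annotation_table(store: AnnotationStore, path: str | Path) -> None:
    """Dump a store as two-column TSV (article, annotation), sorted for determinism."""
    with open(path, "w") as fh:
        fh.write("article\tannotation\n")
        for article in sorted(store.records):
            for annot in sorted(store.records[article]):
                fh.write(f"{article}\t{annot}\n")


def write_citation_pairs(pairs: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write directed citation pairs as two-column TSV with header."""
    with open(path, "w") as fh:
        fh.write("citing\tcited\n")
        for citing, cited in pairs:
            fh.write(f"{citing}\t{cited}\n")
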