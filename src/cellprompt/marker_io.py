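"""Read/write marker and differential-gene data; extract ranked top-k gene lists.

The annotation pipeline starts from an exported differential-expression table
(e.g. Seurat ``FindAllMarkers`` output) rather than from counts: no clustering
or differential testing happens here. Per cluster, genes are ranked by
ascending p-value and the top ``k`` distinct symbols become the marker row sent
to the backend.
"""

from __future__ import annotations

import csv
import io
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: Column-name mappings per input dialect. Values are the file's column names
#: for (gene, cluster, p_value, adj_p_value, effect_size); the last two are
#: optional in the file.
DIALECTS: dict[str, dict[str, str]] = {
    "seurat_findallmarkers": {
        "gene": "gene",
        "cluster_id": "cluster",
        "p_value": "p_val",
        "adj_p_value": "p_val_adj",
        "effect_size": "avg_log2FC",
    },
    "scanpy_export": {
        "gene": "names",
        "cluster_id": "group",
        "p_value": "pvals",
        "adj_p_value": "pvals_adj",
        "effect_size": "logfoldchanges",
    },
}

_REQUIRED_FIELDS = ("gene", "cluster_id", "p_value")
_OPTIONAL_FIELDS = ("adj_p_value", "effect_size")


def _clean_symbol(symbol: str) -> str:
    """Validate and trim a gene symbol; symbols are case-preserved."""
    s = str(symbol).strip()
    if not s:
        raise ValueError("gene symbol must be a non-empty string")
    return s


@dataclass(frozen=True)
class DifferentialGeneRecord:
    """One row of a differential-expression table."""

    gene: str
    cluster_id: str
    p_value: float
    adj_p_value: float | None = None
    effect_size: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "gene", _clean_symbol(self.gene))
        cid = str(self.cluster_id).strip()
        if not cid:
            raise ValueError("cluster_id must be non-empty")
        object.__setattr__(self, "cluster_id", cid)
        if not (0.0 <= self.p_value <= 1.0) or math.isnan(self.p_value):
            raise ValueError(f"p_value {self.p_value!r} outside [0, 1]")
        if self.adj_p_value is not None and not (0.0 <= self.adj_p_value <= 1.0):
            raise ValueError(f"adj_p_value {self.adj_p_value!r} outside [0, 1]")


@dataclass
class DifferentialGeneTable:
    """Ordered collection of differential-gene records; row order = file order."""

    records: list[DifferentialGeneRecord]
    source_dialect: str = "generic"

    def clusters(self) -> list[str]:
        """Cluster ids in order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.records:
            seen.setdefault(rec.cluster_id, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "cluster_id": [r.cluster_id for r in self.records],
                "p_value": [r.p_value for r in self.records],
                "adj_p_value": [r.adj_p_value for r in self.records],
                "effect_size": [r.effect_size for r in self.records],
            }
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ClusterMarkerList:
    """Ordered mapping cluster_id -> ranked top-k gene symbols.

    The unit sent to the backend: one row per cluster. Cluster order is the
    order of first appearance in the source table.
    """

    entries: dict[str, list[str]]
    k_requested: int

    def __post_init__(self):
        if self.k_requested < 1:
            raise ValueError("k_requested must be positive")
        for cid, genes in self.entries.items():
            if len(genes) > self.k_requested:
                raise ValueError(f"cluster {cid!r} has more than k_requested genes")
            if len(set(genes)) != len(genes):
                raise ValueError(f"cluster {cid!r} has duplicate genes")


@dataclass
class MarkerGeneSet:
    """Literature marker genes: ordered mapping cell type name -> gene symbols."""

    entries: dict[str, list[str]]
    species: str = "human"

    def __post_init__(self):
        for name, genes in self.entries.items():
            if not name.strip():
                raise ValueError("cell type name must be non-empty")
            if not genes:
                raise ValueError(f"cell type {name!r} has an empty gene list")
            self.entries[name] = [_clean_symbol(g) for g in genes]

    def __len__(self) -> int:
        return len(self.entries)


Markers = Union[ClusterMarkerList, MarkerGeneSet]


def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_differential_table(
    path: str | Path,
    dialect: str = "seurat_findallmarkers",
    column_map: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> DifferentialGeneTable:
    """Parse a differential-gene table in CSV/TSV form.

    Parameters
    ----------
    path
        File with a header row.
    dialect
        ``seurat_findallmarkers``, ``scanpy_export``, or ``generic``. The
        generic dialect requires ``column_map`` mapping the logical field names
        (``gene``, ``cluster_id``, ``p_value``, optionally ``adj_p_value``,
        ``effect_size``) to the file's column names.
    """
    path = Path(path)
    if dialect == "generic":
        if column_map is None:
            raise ValueError("generic dialect requires a column_map")
        mapping = dict(column_map)
    elif dialect in DIALECTS:
        mapping = DIALECTS[dialect]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    frame = pd.read_csv(path, sep=sep or _infer_sep(path), dtype=str, keep_default_na=False)
    for fld in _REQUIRED_FIELDS:
        col = mapping.get(fld)
        if col is None or col not in frame.columns:
            raise FormatError(f"missing required column {col or fld!r} in {path.name}")

    present_optional = {
        fld: mapping[fld]
        for fld in _OPTIONAL_FIELDS
        if mapping.get(fld) in frame.columns
    }

    records: list[DifferentialGeneRecord] = []
    for idx, row in enumerate(frame.itertuples(index=False)):
        line_no = idx + 2  # 1-based, after the header row
        values = dict(zip(frame.columns, row))

        def _float(col: str, *, required: bool) -> float | None:
            raw = values[col].strip()
            if raw in {"", "NA", "NaN", "nan"}:
                if required:
                    raise FormatError(
                        f"{path.name} line {line_no}: unparseable value {raw!r} in column {col!r}"
                    )
                return None
            try:
                return float(raw)
            except ValueError:
                raise FormatError(
                    f"{path.name} line {line_no}: unparseable value {raw!r} in column {col!r}"
                ) from None

        try:
            records.append(
                DifferentialGeneRecord(
                    gene=values[mapping["gene"]],
                    cluster_id=values[mapping["cluster_id"]],
                    p_value=_float(mapping["p_value"], required=True),
                    adj_p_value=_float(present_optional["adj_p_value"], required=False)
                    if "adj_p_value" in present_optional
                    else None,
                    effect_size=_float(present_optional["effect_size"], required=False)
                    if "effect_size" in present_optional
                    else None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path.name} line {line_no}: {exc}") from exc

    if not records:
        logger.warning("%s contains a header but no data rows", path.name)
    return DifferentialGeneTable(records=records, source_dialect=dialect)


def write_differential_table(
    table: DifferentialGeneTable,
    path: str | Path,
    dialect: str = "seurat_findallmarkers",
) -> None:
    """Write a table back to CSV/TSV using the given dialect's column names."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    mapping = DIALECTS[dialect]
    path = Path(path)
    has_adj = any(r.adj_p_value is not None for r in table.records)
    has_eff = any(r.effect_size is not None for r in table.records)
    cols = [mapping["gene"], mapping["cluster_id"], mapping["p_value"]]
    if has_adj:
        cols.append(mapping["adj_p_value"])
    if has_eff:
        cols.append(mapping["effect_size"])

    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_infer_sep(path))
        writer.writerow(cols)
        for r in table.records:
            row = [r.gene, r.cluster_id, repr(r.p_value)]
            if has_adj:
                row.append("" if r.adj_p_value is None else repr(r.adj_p_value))
            if has_eff:
                row.append("" if r.effect_size is None else repr(r.effect_size))
            writer.writerow(row)


def extract_top_genes(table: DifferentialGeneTable, k: int) -> ClusterMarkerList:
    """Per cluster, take the ``k`` most significant distinct genes.

    Sort is ascending p-value with deterministic tie-breaks: larger absolute
    effect size first (absent effect counts as 0), then gene symbol. Duplicate
    symbols within a cluster keep their best-ranked occurrence only. Clusters
    with fewer than ``k`` genes contribute everything they have, with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not table.records:
        raise ValueError("cannot extract top genes from an empty table")

    entries: dict[str, list[str]] = {}
    for cid in table.clusters():
        recs = [r for r in table.records if r.cluster_id == cid]
        recs.sort(
            key=lambda r: (r.p_value, -abs(r.effect_size or 0.0), r.gene)
        )
        genes: list[str] = []
        seen: set[str] = set()
        for r in recs:
            if r.gene in seen:
                continue
            seen.add(r.gene)
            genes.append(r.gene)
            if len(genes) == k:
                break
        if len(genes) < k:
            logger.warning(
                "cluster %s has only %d distinct genes (k=%d requested)",
                cid, len(genes), k,
            )
        entries[cid] = genes
    return ClusterMarkerList(entries=entries, k_requested=k)


def read_marker_gene_set(path: str | Path, species: str = "human") -> MarkerGeneSet:
    """Read a literature marker-gene list, one cell type per row.

    Two dialects are accepted: TSV with two columns (name, comma-separated
    genes) and CSV where the first cell is the name and every remaining cell
    holds one or more comma-separated genes. Trailing empty tokens are dropped.
    """
    path = Path(path)
    text = path.read_text()
    first_line = text.splitlines()[0] if text.strip() else ""
    delim = "\t" if "\t" in first_line else ","
    entries: dict[str, list[str]] = {}
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    for row_no, row in enumerate(reader, start=1):
        if not row or not any(cell.strip() for cell in row):
            continue
        name = row[0].strip()
        if not name:
            raise FormatError(f"{path.name} line {row_no}: empty cell type name")
        if name in entries:
            raise FormatError(f"{path.name} line {row_no}: duplicate cell type {name!r}")
        genes = [g.strip() for cell in row[1:] for g in cell.split(",") if g.strip()]
        if not genes:
            raise FormatError(f"{path.name} line {row_no}: cell type {name!r} has no genes")
        entries[name] = genes
    return MarkerGeneSet(entries=entries, species=species)


def write_marker_gene_set(markers: MarkerGeneSet, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for name, genes in markers.entries.items():
            writer.writerow([name, ",".join(genes)])


def filter_min_markers(markers: MarkerGeneSet, min_n: int) -> MarkerGeneSet:
    """Keep only cell types with at least ``min_n`` marker genes, in order."""
    kept = {name: list(genes) for name, genes in markers.entries.items() if len(genes) >= min_n}
    if not kept:
        logger.warning("no cell types retain >= %d markers; result is empty", min_n)
    return MarkerGeneSet(entries=kept, species=markers.species)


def format_marker_rows(markers: Markers) -> list[str]:
    """Render one comma-joined row string per cluster / cell type, in order."""
    if not markers.entries:
        raise ValueError("no entries to format")
    return [",".join(genes) for genes in markers.entries.values()]


def read_gene_universe(path: str | Path) -> list[str]:
    """Read a gene universe: one symbol per line, ``#`` comments allowed."""
    symbols: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            symbols.append(line)
    return symbols
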