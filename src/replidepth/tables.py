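"""Taxon-by-replicate count tables and replicate metadata.

The unit of analysis throughout the package is the PCR replicate: one
column of a taxon table is one independent amplification from a DNA
extract.  Biological samples are groups of columns, defined by the
accompanying :class:`ReplicateMetadata`.

Canonical on-disk format is TSV (first column taxon id, optional second
column a semicolon-delimited lineage of ``rank:value`` tokens, remaining
columns integer counts headed by replicate ids).  A minimal dense
JSON-BIOM reader/writer is provided for interoperability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonTable",
    "SampleType",
    "ReplicateMetadata",
    "read_taxon_table",
    "write_taxon_table",
    "read_metadata",
    "write_metadata",
    "aggregate_by_rank",
    "prune_empty",
]

LINEAGE_COLUMN = "lineage"
UNASSIGNED = "unassigned"
OTHER = "other"


class TableFormatError(ValueError):
    """Raised when a counts file cannot be parsed into a valid table."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise TableFormatError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class TaxonTable:
    """Dense non-negative integer read counts, taxa (rows) x replicates (columns).

    Parameters
    ----------
    taxon_ids :
        Unique row labels.
    replicate_ids :
        Unique column labels (one per PCR replicate).
    counts :
        Integer matrix, shape ``(len(taxon_ids), len(replicate_ids))``.
    lineage :
        Optional per-taxon lineage string of semicolon-delimited
        ``rank:value`` tokens (e.g. ``"family:Poaceae;genus:Poa"``).  Taxa
        identified only to a higher rank simply carry fewer tokens.
    """

    taxon_ids: list[str]
    replicate_ids: list[str]
    counts: np.ndarray
    lineage: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise TableFormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if np.issubdtype(self.counts.dtype, np.floating) and np.all(
                self.counts == np.floor(self.counts)
            ):
                self.counts = self.counts.astype(np.int64)
            else:
                raise TableFormatError("counts must be integers")
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableFormatError(
                f"negative count at taxon {self.taxon_ids[i]!r}, "
                f"replicate {self.replicate_ids[j]!r}"
            )
        if self.counts.shape != (len(self.taxon_ids), len(self.replicate_ids)):
            raise TableFormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.replicate_ids)} replicates"
            )
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.replicate_ids, "replicate")
        if self.lineage is not None and len(self.lineage) != len(self.taxon_ids):
            raise TableFormatError("lineage length must match taxon_ids")

    # -- basic accessors -------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_ids)

    @property
    def depths(self) -> np.ndarray:
        """Per-replicate library depth (column sums)."""
        return self.counts.sum(axis=0)

    def column(self, replicate_id: str) -> np.ndarray:
        return self.counts[:, self.replicate_ids.index(replicate_id)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.replicate_ids)

    # -- subsetting ------------------------------------------------------

    def select_replicates(self, ids: Iterable[str]) -> "TaxonTable":
        ids = list(ids)
        idx = [self.replicate_ids.index(r) for r in ids]
        return replace(self, replicate_ids=ids, counts=self.counts[:, idx])

    def drop_replicates(self, ids: Iterable[str]) -> "TaxonTable":
        drop = set(ids)
        keep = [r for r in self.replicate_ids if r not in drop]
        return self.select_replicates(keep)

    def select_taxa(self, ids: Iterable[str]) -> "TaxonTable":
        ids = list(ids)
        idx = [self.taxon_ids.index(t) for t in ids]
        lin = [self.lineage[i] for i in idx] if self.lineage is not None else None
        return replace(self, taxon_ids=ids, counts=self.counts[idx, :], lineage=lin)

    def drop_taxa(self, ids: Iterable[str]) -> "TaxonTable":
        drop = set(ids)
        keep = [t for t in self.taxon_ids if t not in drop]
        return self.select_taxa(keep)


class SampleType(str, Enum):
    SAMPLE = "sample"
    EXTRACTION_CONTROL = "extraction_control"
    PCR_CONTROL = "pcr_control"
    POSITIVE_CONTROL = "positive_control"


NEGATIVE_CONTROL_TYPES = (SampleType.EXTRACTION_CONTROL, SampleType.PCR_CONTROL)


@dataclass
class ReplicateMetadata:
    """Maps each replicate to its DNA extract, marker and sample type."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("replicate_id", "extract_id", "marker", "sample_type")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records)
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise TableFormatError(f"metadata missing columns: {missing}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["sample_type"] = df["sample_type"].map(lambda s: SampleType(s).value)
        if df["replicate_id"].duplicated().any():
            dup = df.loc[df["replicate_id"].duplicated(), "replicate_id"].iloc[0]
            raise TableFormatError(f"duplicate replicate id in metadata: {dup!r}")
        self.records = df.reset_index(drop=True)

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str, str]]) -> "ReplicateMetadata":
        return cls(pd.DataFrame(rows, columns=list(cls.REQUIRED)))

    def _of_type(self, types: tuple[SampleType, ...]) -> list[str]:
        vals = {t.value for t in types}
        return list(self.records.loc[self.records["sample_type"].isin(vals), "replicate_id"])

    @property
    def sample_ids(self) -> list[str]:
        return self._of_type((SampleType.SAMPLE,))

    @property
    def negative_control_ids(self) -> list[str]:
        """Extraction and PCR negatives, pooled into one control class."""
        return self._of_type(NEGATIVE_CONTROL_TYPES)

    @property
    def positive_control_ids(self) -> list[str]:
        return self._of_type((SampleType.POSITIVE_CONTROL,))

    def extract_of(self, replicate_id: str) -> str:
        row = self.records.loc[self.records["replicate_id"] == replicate_id]
        if row.empty:
            raise KeyError(replicate_id)
        return str(row["extract_id"].iloc[0])

    def extracts(self) -> dict[str, list[str]]:
        """Sample replicate ids grouped by extract, in stable order."""
        samp = self.records[self.records["sample_type"] == SampleType.SAMPLE.value]
        out: dict[str, list[str]] = {}
        for _, row in samp.iterrows():
            out.setdefault(str(row["extract_id"]), []).append(str(row["replicate_id"]))
        return out

    def validate_against(self, table: TaxonTable) -> None:
        known = set(self.records["replicate_id"])
        missing = [r for r in table.replicate_ids if r not in known]
        if missing:
            raise TableFormatError(f"replicates without metadata: {missing}")
        if not set(table.replicate_ids) & set(self.sample_ids):
            raise TableFormatError("at least one sample_type=sample replicate is required")

    def subset(self, replicate_ids: Iterable[str]) -> "ReplicateMetadata":
        keep = set(replicate_ids)
        return ReplicateMetadata(self.records[self.records["replicate_id"].isin(keep)])


# ---------------------------------------------------------------------------
# Readers / writers


def read_taxon_table(path: str | Path, format: str = "tsv") -> TaxonTable:
    """Read a counts table; ``format`` is ``"tsv"`` or ``"biom_json"``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom_json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def write_taxon_table(table: TaxonTable, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        _write_tsv(table, path)
    elif format == "biom_json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> TaxonTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise TableFormatError(f"{path}: empty file")
        cols = header.split("\t")
        has_lineage = len(cols) >= 2 and cols[1] == LINEAGE_COLUMN
        first_count_col = 2 if has_lineage else 1
        replicate_ids = cols[first_count_col:]
        taxon_ids: list[str] = []
        lineage: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise TableFormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            taxon_ids.append(fields[0])
            if has_lineage:
                lineage.append(fields[1])
            row = []
            for j, cell in enumerate(fields[first_count_col:]):
                try:
                    val = int(cell)
                except ValueError:
                    raise TableFormatError(
                        f"{path}:{lineno}: non-integer count {cell!r} in "
                        f"replicate {replicate_ids[j]!r}"
                    ) from None
                if val < 0:
                    raise TableFormatError(
                        f"{path}:{lineno}: negative count in replicate {replicate_ids[j]!r}"
                    )
                row.append(val)
            rows.append(row)
    counts = (
        np.array(rows, dtype=np.int64)
        if rows
        else np.zeros((0, len(replicate_ids)), dtype=np.int64)
    )
    return TaxonTable(
        taxon_ids=taxon_ids,
        replicate_ids=replicate_ids,
        counts=counts,
        lineage=lineage if has_lineage else None,
    )


def _write_tsv(table: TaxonTable, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        cols = ["taxon_id"]
        if table.lineage is not None:
            cols.append(LINEAGE_COLUMN)
        cols.extend(table.replicate_ids)
        fh.write("\t".join(cols) + "\n")
        for i, tid in enumerate(table.taxon_ids):
            fields = [tid]
            if table.lineage is not None:
                fields.append(table.lineage[i])
            fields.extend(str(int(c)) for c in table.counts[i])
            fh.write("\t".join(fields) + "\n")


def _read_biom_json(path: Path) -> TaxonTable:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise TableFormatError("only dense JSON-BIOM tables are supported")
    taxon_ids = [r["id"] for r in doc["rows"]]
    lineage = None
    if any((r.get("metadata") or {}).get(LINEAGE_COLUMN) is not None for r in doc["rows"]):
        lineage = [(r.get("metadata") or {}).get(LINEAGE_COLUMN, "") or "" for r in doc["rows"]]
    replicate_ids = [c["id"] for c in doc["columns"]]
    data = np.array(doc["data"], dtype=float) if doc["data"] else np.zeros(
        (0, len(replicate_ids))
    )
    data = data.reshape(len(taxon_ids), len(replicate_ids)) if len(taxon_ids) else np.zeros(
        (0, len(replicate_ids))
    )
    if not np.all(data == np.floor(data)):
        raise TableFormatError("non-integer count in BIOM data")
    return TaxonTable(taxon_ids, replicate_ids, data.astype(np.int64), lineage)


def _write_biom_json(table: TaxonTable, path: Path) -> None:
    rows = []
    for i, tid in enumerate(table.taxon_ids):
        meta = None
        if table.lineage is not None:
            meta = {LINEAGE_COLUMN: table.lineage[i]}
        rows.append({"id": tid, "metadata": meta})
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "Taxon table",
        "generated_by": "replidepth",
        "matrix_type": "dense",
        "matrix_element_type": "int",
        "shape": [table.n_taxa, table.n_replicates],
        "rows": rows,
        "columns": [{"id": r, "metadata": None} for r in table.replicate_ids],
        "data": table.counts.tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def read_metadata(path: str | Path) -> ReplicateMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return ReplicateMetadata(df)


def write_metadata(meta: ReplicateMetadata, path: str | Path) -> None:
    meta.records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Aggregation / pruning


def _lineage_rank_value(lineage: str, rank: str) -> str | None:
    for token in lineage.split(";"):
        token = token.strip()
        if not token:
            continue
        if ":" in token:
            r, v = token.split(":", 1)
            if r == rank:
                return v
    return None


def aggregate_by_rank(table: TaxonTable, rank: str, top_k: int | None = None) -> TaxonTable:
    """Sum taxon rows within a lineage rank (e.g. family).

    Taxa lacking the rank are pooled into ``"unassigned"``.  With
    ``top_k``, only the top-k rank values by total reads are kept and the
    remainder pooled into ``"other"``.  Per-replicate totals are conserved
    exactly.
    """
    if top_k is not None and top_k < 1:
        raise ValueError("top_k must be a positive integer")
    if table.n_taxa == 0:
        return TaxonTable(
            [], list(table.replicate_ids), np.zeros((0, table.n_replicates), dtype=np.int64)
        )
    # A rank that appears in no lineage of a lineage-bearing table is a typo,
    # not a request to pool everything into "unassigned".
    if table.lineage is not None and any(":" in (l or "") for l in table.lineage):
        if all(_lineage_rank_value(l or "", rank) is None for l in table.lineage):
            raise ValueError(f"unknown rank {rank!r}: not present in any lineage")
    groups: dict[str, np.ndarray] = {}
    order: list[str] = []
    for i in range(table.n_taxa):
        lin = table.lineage[i] if table.lineage is not None else ""
        value = _lineage_rank_value(lin, rank) if lin else None
        key = value if value is not None else UNASSIGNED
        if key not in groups:
            groups[key] = np.zeros(table.n_replicates, dtype=np.int64)
            order.append(key)
        groups[key] += table.counts[i]
    if top_k is not None:
        ranked = sorted(order, key=lambda k: (-int(groups[k].sum()), k))
        keep = set(ranked[:top_k])
        pooled = np.zeros(table.n_replicates, dtype=np.int64)
        new_order = [k for k in order if k in keep]
        for k in order:
            if k not in keep:
                pooled += groups[k]
        groups = {k: groups[k] for k in new_order}
        if pooled.sum() > 0 or len(new_order) < len(order):
            groups[OTHER] = pooled
            new_order.append(OTHER)
        order = new_order
    counts = np.vstack([groups[k] for k in order]) if order else np.zeros(
        (0, table.n_replicates), dtype=np.int64
    )
    return TaxonTable(order, list(table.replicate_ids), counts)


def prune_empty(table: TaxonTable, drop_empty_replicates: bool = False) -> TaxonTable:
    """Remove all-zero taxon rows (and optionally zero-depth columns)."""
    keep_rows = table.counts.sum(axis=1) > 0 if table.n_taxa else np.zeros(0, dtype=bool)
    out = table.select_taxa([t for t, k in zip(table.taxon_ids, keep_rows) if k])
    if drop_empty_replicates:
        depths = out.counts.sum(axis=0) if out.n_taxa else np.zeros(out.n_replicates)
        out = out.select_replicates(
            [r for r, d in zip(out.replicate_ids, depths) if d > 0]
        )
    return out
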