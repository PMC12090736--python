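"""Tabular containers and readers/writers for every file the pipeline touches.

All tables travel as delimited text (TSV canonical, CSV accepted, chosen by
file extension or an explicit ``sep``); trees travel as Newick. Readers
preserve row/column order from the file and either parse every row or raise —
there is no silent row dropping. ``write_*``/``read_*`` pairs round-trip
losslessly up to float formatting at the stated precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .taxonomy import RANKS, HostLineage, Rank, parse_lineage

__all__ = [
    "PredictionTable",
    "LinkageTable",
    "AbundanceTable",
    "CoverageRecord",
    "read_prediction_table",
    "write_prediction_table",
    "read_linkage_table",
    "write_linkage_table",
    "read_abundance",
    "write_abundance",
    "read_tree",
    "write_tree",
]

_FLOAT_FMT = "%.10g"


def _sep_for(path, sep: Optional[str]) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def _sorted_by_confidence(df: pd.DataFrame) -> pd.DataFrame:
    # Deterministic ordering: confidence descending, ties broken by the
    # lexicographically smallest serialised lineage.
    key = df["lineage"].map(lambda l: l.serialize())
    return (
        df.assign(_key=key)
        .sort_values(["confidence", "_key"], ascending=[False, True], kind="mergesort")
        .drop(columns="_key")
    )


@dataclass
class PredictionTable:
    """Per-contig ranked host predictions (the shape of iPHoP output).

    ``rows`` has columns ``contig_id`` (str), ``lineage`` (:class:`HostLineage`)
    and ``confidence`` (float in [0, 100]). A contig may appear in several
    rows, one per predicted host.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"contig_id", "lineage", "confidence"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"PredictionTable missing columns: {sorted(missing)}")
        if len(self.rows):
            conf = pd.to_numeric(self.rows["confidence"], errors="raise")
            self.rows = self.rows.assign(
                contig_id=self.rows["contig_id"].astype(str),
                confidence=conf.astype(float),
            )
            if (self.rows["contig_id"] == "").any():
                raise ValueError("empty contig_id in prediction table")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def contigs(self) -> set[str]:
        return set(self.rows["contig_id"])

    def lineages_for(self, contig_id: str) -> list[HostLineage]:
        """Predicted lineages for one contig, most confident first."""
        sub = self.rows[self.rows["contig_id"] == contig_id]
        return list(_sorted_by_confidence(sub)["lineage"])

    def best_for(self, contig_id: str) -> tuple[HostLineage, float]:
        sub = _sorted_by_confidence(self.rows[self.rows["contig_id"] == contig_id])
        if sub.empty:
            raise KeyError(contig_id)
        row = sub.iloc[0]
        return row["lineage"], float(row["confidence"])

    def grouped(self) -> dict[str, list[tuple[HostLineage, float]]]:
        """All contigs at once: contig -> [(lineage, confidence), ...] sorted
        most confident first (bulk form of :meth:`lineages_for`)."""
        ordered = _sorted_by_confidence(self.rows)
        out: dict[str, list[tuple[HostLineage, float]]] = {}
        for cid, lin, conf in zip(
            ordered["contig_id"], ordered["lineage"], ordered["confidence"]
        ):
            out.setdefault(cid, []).append((lin, float(conf)))
        return out


@dataclass
class LinkageTable:
    """Per-contig experimentally linked hosts (proximity ligation / Hi-C).

    ``rows`` has columns ``contig_id``, ``lineage`` and ``link_rank``
    (1 = strongest link); within a contig link ranks are unique.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"contig_id", "lineage", "link_rank"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"LinkageTable missing columns: {sorted(missing)}")
        if len(self.rows):
            rank = pd.to_numeric(self.rows["link_rank"], errors="raise").astype(int)
            if (rank < 1).any():
                raise ValueError("link_rank must be a positive integer")
            self.rows = self.rows.assign(
                contig_id=self.rows["contig_id"].astype(str), link_rank=rank
            )
            dup = self.rows.duplicated(subset=["contig_id", "link_rank"])
            if dup.any():
                bad = self.rows.loc[dup, "contig_id"].unique().tolist()
                raise ValueError(f"duplicate link_rank within contig(s): {bad}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def contigs(self) -> set[str]:
        return set(self.rows["contig_id"])

    def lineages_for(self, contig_id: str) -> list[HostLineage]:
        """Linked lineages for one contig, strongest link first."""
        sub = self.rows[self.rows["contig_id"] == contig_id]
        return list(sub.sort_values("link_rank", kind="mergesort")["lineage"])

    def grouped(self) -> dict[str, list[HostLineage]]:
        """All contigs at once: contig -> lineages, strongest link first."""
        ordered = self.rows.sort_values("link_rank", kind="mergesort")
        out: dict[str, list[HostLineage]] = {}
        for cid, lin in zip(ordered["contig_id"], ordered["lineage"]):
            out.setdefault(cid, []).append(lin)
        return out

    @classmethod
    def from_strengths(cls, rows: pd.DataFrame) -> "LinkageTable":
        """Build from a table with a ``strength`` column instead of ranks.

        Ranks are assigned per contig by descending strength, ties broken by
        the lexicographically smallest serialised lineage.
        """
        key = rows["lineage"].map(lambda l: l.serialize())
        ordered = rows.assign(_key=key).sort_values(
            ["contig_id", "strength", "_key"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        ordered["link_rank"] = ordered.groupby("contig_id").cumcount() + 1
        return cls(ordered.drop(columns=["_key", "strength"]).reset_index(drop=True))


@dataclass
class AbundanceTable:
    """A feature x sample numeric matrix with feature and sample metadata.

    ``values`` is features (rows) x samples (columns), all entries >= 0.
    ``feature_meta`` (indexed by feature) may carry ``length_bp``, ``phf``,
    ``prophage``, ``amg_count``. ``sample_meta`` (indexed by sample) carries
    ``individual_id`` plus optional ``time_index``, ``diagnosis``,
    ``dysbiotic``. ``time_index`` must be unique within an individual.
    """

    values: pd.DataFrame
    feature_meta: Optional[pd.DataFrame] = None
    sample_meta: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError(f"duplicate feature ids: "
                             f"{v.index[v.index.duplicated()].unique().tolist()}")
        if v.columns.has_duplicates:
            raise ValueError(f"duplicate sample ids: "
                             f"{v.columns[v.columns.duplicated()].unique().tolist()}")
        arr = v.to_numpy()
        if len(arr) and not np.issubdtype(arr.dtype, np.number):
            raise ValueError("abundance matrix must be numeric")
        if len(arr) and np.isnan(arr.astype(float)).any():
            raise ValueError("abundance matrix contains missing values")
        if len(arr) and (arr < 0).any():
            raise ValueError("abundance matrix contains negative values")
        if self.feature_meta is not None:
            missing = v.index.difference(self.feature_meta.index)
            if len(missing):
                raise ValueError(
                    f"features absent from feature metadata: {missing.tolist()}"
                )
            self.feature_meta = self.feature_meta.loc[v.index]
        if self.sample_meta is not None:
            missing = v.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ValueError(
                    f"samples absent from sample metadata: {missing.tolist()}"
                )
            self.sample_meta = self.sample_meta.loc[v.columns]
            if "individual_id" not in self.sample_meta.columns:
                raise ValueError("sample metadata lacks individual_id")
            if "time_index" in self.sample_meta.columns:
                t = self.sample_meta.dropna(subset=["time_index"])
                dup = t.duplicated(subset=["individual_id", "time_index"])
                if dup.any():
                    raise ValueError(
                        "duplicate time_index within individual(s): "
                        f"{t.loc[dup, 'individual_id'].unique().tolist()}"
                    )

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return len(self.values.index)

    @property
    def n_samples(self) -> int:
        return len(self.values.columns)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(
            self.values.copy(),
            None if self.feature_meta is None else self.feature_meta.copy(),
            None if self.sample_meta is None else self.sample_meta.copy(),
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        keep = [s for s in self.samples if s in set(sample_ids)]
        return AbundanceTable(
            self.values[keep],
            self.feature_meta,
            None if self.sample_meta is None else self.sample_meta.loc[keep],
        )

    def equals(self, other: "AbundanceTable", atol: float = 1e-9) -> bool:
        if list(self.features) != list(other.features):
            return False
        if list(self.samples) != list(other.samples):
            return False
        if not np.allclose(self.values.to_numpy(float),
                           other.values.to_numpy(float), atol=atol):
            return False
        return True


@dataclass
class CoverageRecord:
    """Per (feature, sample) breadth of coverage and mapped read counts."""

    breadth: pd.DataFrame
    mapped_reads: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        b = self.breadth.to_numpy(float)
        if b.size and ((b < 0) | (b > 1)).any():
            raise ValueError("breadth of coverage must lie in [0, 1]")
        if self.mapped_reads is not None:
            r = self.mapped_reads.to_numpy(float)
            if r.size and (r < 0).any():
                raise ValueError("mapped read counts must be >= 0")


# ---------------------------------------------------------------------------
# prediction / linkage tables
# ---------------------------------------------------------------------------

_RANK_COLS = [str(r) for r in RANKS]


def _lineages_from_frame(df: pd.DataFrame, dialect: str) -> pd.Series:
    """Extract HostLineage objects from either a lineage column or per-rank
    columns (``domain`` ... ``species``)."""
    if "lineage" in df.columns:
        out = []
        for i, s in enumerate(df["lineage"].astype(str)):
            try:
                out.append(parse_lineage(s, dialect))
            except Exception as exc:
                raise ValueError(f"row {i}: {exc}") from exc
        return pd.Series(out, index=df.index)
    rank_cols = [c for c in _RANK_COLS if c in df.columns]
    if "domain" not in rank_cols:
        raise ValueError(
            "table needs either a 'lineage' column or per-rank columns "
            "including 'domain'"
        )
    names_by_rank = {
        c: df[c].fillna("").astype(str).str.strip() if c in df.columns
        else pd.Series("", index=df.index)
        for c in _RANK_COLS
    }
    out = []
    for i in df.index:
        names = tuple(names_by_rank[c].loc[i] for c in _RANK_COLS)
        if not names[0]:
            raise ValueError(f"row {i}: lineage has no domain name")
        out.append(HostLineage(names))
    return pd.Series(out, index=df.index)


def read_prediction_table(
    path,
    dialect: str = "auto",
    sep: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> PredictionTable:
    """Read a host-prediction table.

    Expected columns (after applying ``column_map``, which maps the file's
    column names to canonical ones): ``contig_id``, ``confidence``, and
    either ``lineage`` or per-rank columns ``domain`` ... ``species``.
    """
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in ("contig_id", "confidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    bad = conf.isna()
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based, counting the header
        raise ValueError(f"{path}: non-numeric confidence at file line(s) {rows}")
    lineages = _lineages_from_frame(df, dialect)
    return PredictionTable(
        pd.DataFrame(
            {"contig_id": df["contig_id"], "lineage": lineages, "confidence": conf}
        ).reset_index(drop=True)
    )


def write_prediction_table(table: PredictionTable, path, sep: Optional[str] = None) -> None:
    out = pd.DataFrame(
        {
            "contig_id": table.rows["contig_id"],
            "lineage": table.rows["lineage"].map(lambda l: l.serialize()),
            "confidence": table.rows["confidence"],
        }
    )
    out.to_csv(path, sep=_sep_for(path, sep), index=False, float_format=_FLOAT_FMT)


def read_linkage_table(
    path,
    dialect: str = "auto",
    sep: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> LinkageTable:
    """Read a Hi-C linkage table (columns ``contig_id``, ``link_rank`` or
    ``strength``, and a lineage column as for predictions)."""
    df = pd.read_csv(path, sep=_sep_for(path, sep), dtype=str)
    if column_map:
        df = df.rename(columns=dict(column_map))
    if "contig_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'contig_id'")
    lineages = _lineages_from_frame(df, dialect)
    if "link_rank" in df.columns:
        rank = pd.to_numeric(df["link_rank"], errors="coerce")
        if rank.isna().any():
            rows = (df.index[rank.isna()] + 2).tolist()
            raise ValueError(f"{path}: non-numeric link_rank at file line(s) {rows}")
        return LinkageTable(
            pd.DataFrame(
                {"contig_id": df["contig_id"], "lineage": lineages,
                 "link_rank": rank.astype(int)}
            ).reset_index(drop=True)
        )
    if "strength" in df.columns:
        strength = pd.to_numeric(df["strength"], errors="raise")
        return LinkageTable.from_strengths(
            pd.DataFrame(
                {"contig_id": df["contig_id"], "lineage": lineages,
                 "strength": strength}
            ).reset_index(drop=True)
        )
    raise ValueError(f"{path}: needs a 'link_rank' or 'strength' column")


def write_linkage_table(table: LinkageTable, path, sep: Optional[str] = None) -> None:
    out = pd.DataFrame(
        {
            "contig_id": table.rows["contig_id"],
            "lineage": table.rows["lineage"].map(lambda l: l.serialize()),
            "link_rank": table.rows["link_rank"],
        }
    )
    out.to_csv(path, sep=_sep_for(path, sep), index=False)


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------

def read_abundance(
    path_matrix,
    path_feature_meta=None,
    path_sample_meta=None,
    sep: Optional[str] = None,
) -> AbundanceTable:
    """Read a feature x sample matrix plus optional metadata tables.

    The matrix file has features as rows (first column = feature id) and
    samples as columns. ``NA`` or empty cells are legal in metadata but not
    in the numeric matrix.
    """
    values = pd.read_csv(path_matrix, sep=_sep_for(path_matrix, sep), index_col=0)
    values.index = values.index.astype(str)
    feature_meta = sample_meta = None
    if path_feature_meta is not None:
        feature_meta = pd.read_csv(
            path_feature_meta, sep=_sep_for(path_feature_meta, sep), index_col=0
        )
        feature_meta.index = feature_meta.index.astype(str)
    if path_sample_meta is not None:
        sample_meta = pd.read_csv(
            path_sample_meta, sep=_sep_for(path_sample_meta, sep), index_col=0
        )
        sample_meta.index = sample_meta.index.astype(str)
        if "dysbiotic" in sample_meta.columns:
            sample_meta["dysbiotic"] = sample_meta["dysbiotic"].map(
                {"True": True, "False": False, True: True, False: False}
            )
    return AbundanceTable(values, feature_meta, sample_meta)


def write_abundance(
    table: AbundanceTable,
    path_matrix,
    path_feature_meta=None,
    path_sample_meta=None,
    sep: Optional[str] = None,
) -> None:
    table.values.to_csv(
        path_matrix, sep=_sep_for(path_matrix, sep), float_format=_FLOAT_FMT,
        index_label="feature_id",
    )
    if path_feature_meta is not None and table.feature_meta is not None:
        table.feature_meta.to_csv(
            path_feature_meta, sep=_sep_for(path_feature_meta, sep),
            index_label="feature_id",
        )
    if path_sample_meta is not None and table.sample_meta is not None:
        table.sample_meta.to_csv(
            path_sample_meta, sep=_sep_for(path_sample_meta, sep),
            index_label="sample_id",
        )


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree and validate tip-label uniqueness and
    non-negative branch lengths."""
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        dupes = sorted({n for n in tips if tips.count(n) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValueError(f"negative branch length at {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")
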