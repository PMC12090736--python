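"""Per-rank concordance between experimentally linked and predicted hosts.

For every viral contig that has both a computational host prediction and an
experimental (proximity-ligation) host assignment, the two host sets are
compared at each rank from phylum to genus under three stringencies:

* ``strict`` — the most confident prediction must match the top-ranked
  experimental hit;
* ``top_vs_any`` — the most confident prediction must match *any*
  experimental hit;
* ``any_vs_any`` — any prediction may match any experimental hit.

Percent concordance is ``100 * n_concordant / n_total`` where ``n_total`` is
the number of contigs in the intersection of the two tables — the same
denominator at every rank and mode. Contigs whose host lacks a name at a
rank are counted discordant at that rank by default; ``drop_unnamed`` per
rank can exclude them from the denominator instead.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import LinkageTable, PredictionTable
from .taxonomy import CONCORDANCE_RANKS, HostLineage, Rank, names_match_at

__all__ = [
    "ComparisonMode",
    "ConcordanceReport",
    "intersect_contigs",
    "is_concordant",
    "concordance_report",
]


class ComparisonMode(str, enum.Enum):
    """Matching stringency for contigs with multiple hosts on either side."""

    STRICT = "strict"
    TOP_VS_ANY = "top_vs_any"
    ANY_VS_ANY = "any_vs_any"


MODES: tuple[ComparisonMode, ...] = tuple(ComparisonMode)


def intersect_contigs(pred: PredictionTable, link: LinkageTable) -> set[str]:
    """Contigs with both a prediction and an experimental linkage — the
    concordance denominator."""
    shared = pred.contigs & link.contigs
    if not shared:
        warnings.warn(
            "no contigs shared between prediction and linkage tables; "
            "concordance is undefined",
            stacklevel=2,
        )
    return shared


def is_concordant(
    pred_lineages: Sequence[HostLineage],
    hic_lineages: Sequence[HostLineage],
    rank: Rank,
    mode: ComparisonMode,
) -> bool:
    """Apply one matching rule to one contig's two host lists.

    ``pred_lineages`` must be ordered most-confident-first and
    ``hic_lineages`` strongest-link-first; both must be non-empty.
    """
    if not pred_lineages or not hic_lineages:
        raise ValueError("is_concordant requires non-empty host lists")
    mode = ComparisonMode(mode)
    if mode is ComparisonMode.STRICT:
        return names_match_at(pred_lineages[0], hic_lineages[0], rank)
    if mode is ComparisonMode.TOP_VS_ANY:
        return any(names_match_at(pred_lineages[0], h, rank) for h in hic_lineages)
    return any(
        names_match_at(p, h, rank) for p in pred_lineages for h in hic_lineages
    )


@dataclass
class ConcordanceReport:
    """Counts and percentages per (rank, mode), plus contig accounting.

    ``table`` has one row per (rank, mode) with columns ``rank``, ``mode``,
    ``n_concordant``, ``n_total``, ``percent``. When the denominator is
    empty, ``percent`` is NaN and ``undefined`` is True.
    """

    table: pd.DataFrame
    n_contigs_predicted: int
    n_contigs_linked: int
    n_contigs_both: int

    @property
    def undefined(self) -> bool:
        return self.n_contigs_both == 0

    def percent(self, rank: Rank, mode: ComparisonMode) -> float:
        row = self.table[
            (self.table["rank"] == str(rank))
            & (self.table["mode"] == ComparisonMode(mode).value)
        ]
        if row.empty:
            raise KeyError((rank, mode))
        return float(row["percent"].iloc[0])

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep, index=False, float_format="%.1f")


def concordance_report(
    pred: PredictionTable,
    link: LinkageTable,
    ranks: Sequence[Rank] = CONCORDANCE_RANKS,
    modes: Sequence[ComparisonMode] = MODES,
    drop_unnamed: bool = False,
) -> ConcordanceReport:
    """Score every shared contig at every (rank, mode) combination.

    With ``drop_unnamed=True``, contigs for which *neither* side carries a
    name at a given rank are removed from that rank's denominator instead of
    counting as discordant.
    """
    shared = sorted(intersect_contigs(pred, link))
    pred_grouped = pred.grouped()
    hic_grouped = link.grouped()
    pred_lists = {c: [l for l, _ in pred_grouped[c]] for c in shared}
    hic_lists = {c: hic_grouped[c] for c in shared}

    rows = []
    for rank in ranks:
        for mode in modes:
            mode = ComparisonMode(mode)
            n_total = 0
            n_conc = 0
            for c in shared:
                if drop_unnamed and not any(
                    l.name_at(rank)
                    for l in list(pred_lists[c]) + list(hic_lists[c])
                ):
                    continue
                n_total += 1
                if is_concordant(pred_lists[c], hic_lists[c], rank, mode):
                    n_conc += 1
            percent = 100.0 * n_conc / n_total if n_total else float("nan")
            rows.append(
                {
                    "rank": str(rank),
                    "mode": mode.value,
                    "n_concordant": n_conc,
                    "n_total": n_total,
                    "percent": percent,
                }
            )
    return ConcordanceReport(
        table=pd.DataFrame(rows),
        n_contigs_predicted=len(pred.contigs),
        n_contigs_linked=len(link.contigs),
        n_contigs_both=len(shared),
    )
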