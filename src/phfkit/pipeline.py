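"""vOTU-level to PHF-level transformations.

The phage host family (PHF) of a contig is the family of its most confident
host prediction; contigs with no prediction carry the sentinel family
``"Unknown"``. This module implements best-prediction selection, relative
abundance, the unknown-host sample filter, family-level agglomeration,
breadth-based presence calling, Good's coverage, the read-depth sample
filter, ANI/AF dereplication into vOTUs, per-individual prevalence, and
AMG-density summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import AbundanceTable, CoverageRecord, PredictionTable
from .taxonomy import HostLineage, Rank

__all__ = [
    "UNKNOWN",
    "PHFCall",
    "PHFAssignment",
    "PairwiseHit",
    "assign_phf",
    "to_relative_abundance",
    "filter_unknown_fraction",
    "agglomerate",
    "call_presence",
    "goods_coverage",
    "filter_low_depth",
    "dereplicate",
    "prevalence",
    "prevalent_features",
    "prevalent_mass",
    "amg_density",
    "select_paired_individuals",
    "filter_feature_meta",
]

#: Sentinel family for contigs without a host prediction.
UNKNOWN = "Unknown"


@dataclass(frozen=True)
class PHFCall:
    family: str
    confidence: Optional[float]


@dataclass
class PHFAssignment:
    """contig_id -> (host family, confidence of the winning prediction)."""

    calls: dict[str, PHFCall]

    def family_of(self, contig_id: str) -> str:
        call = self.calls.get(contig_id)
        return UNKNOWN if call is None else call.family

    def families(self, contig_ids: Iterable[str]) -> pd.Series:
        ids = list(contig_ids)
        return pd.Series([self.family_of(c) for c in ids], index=ids, name="phf")

    @property
    def n_unknown(self) -> int:
        return sum(1 for c in self.calls.values() if c.family == UNKNOWN)

    def __len__(self) -> int:
        return len(self.calls)


@dataclass(frozen=True)
class PairwiseHit:
    """One blast-style alignment between two contigs.

    ``ani`` is percent nucleotide identity; ``alignment_fraction`` is percent
    of the *shorter* sequence covered by the alignment.
    """

    query_id: str
    target_id: str
    ani: float
    alignment_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.ani <= 100 and 0 <= self.alignment_fraction <= 100):
            raise ValueError("ani and alignment_fraction must lie in [0, 100]")


def assign_phf(pred: PredictionTable, contigs: Iterable[str]) -> PHFAssignment:
    """Pick one host family per contig: the family of the most confident
    prediction (ties broken by the lexicographically smallest serialised
    lineage). Contigs absent from ``pred``, or whose best prediction has an
    empty family name, are assigned ``"Unknown"``.
    """
    calls: dict[str, PHFCall] = {}
    best = {c: lins[0] for c, lins in pred.grouped().items()}
    for contig in contigs:
        if contig in best:
            lineage, conf = best[contig]
            family = lineage.name_at(Rank.FAMILY) or UNKNOWN
            calls[contig] = PHFCall(family, conf)
        else:
            calls[contig] = PHFCall(UNKNOWN, None)
    return PHFAssignment(calls)


def to_relative_abundance(t: AbundanceTable) -> AbundanceTable:
    """Scale each sample (column) to sum to 1. Zero-sum samples are an error."""
    totals = t.values.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero-sum sample(s): {zero.index.tolist()}")
    return AbundanceTable(t.values.div(totals, axis=1), t.feature_meta, t.sample_meta)


def _phf_labels(t: AbundanceTable, assign: Optional[PHFAssignment]) -> pd.Series:
    if assign is not None:
        return assign.families(t.features)
    if t.feature_meta is not None and "phf" in t.feature_meta.columns:
        return t.feature_meta["phf"].fillna(UNKNOWN).astype(str)
    raise ValueError("no PHF assignment given and feature metadata lacks 'phf'")


def filter_unknown_fraction(
    t: AbundanceTable,
    assign: Optional[PHFAssignment] = None,
    max_unknown: float = 0.30,
) -> AbundanceTable:
    """Keep samples whose unknown-host community fraction is strictly below
    ``max_unknown`` (default 30%). ``t`` must be relative abundance."""
    labels = _phf_labels(t, assign)
    unknown_mass = t.values.loc[labels == UNKNOWN].sum(axis=0)
    keep = unknown_mass[unknown_mass < max_unknown].index.tolist()
    if not keep:
        warnings.warn("unknown-host filter removed every sample", stacklevel=2)
    return t.select_samples(keep)


def agglomerate(
    t: AbundanceTable,
    assign: Optional[PHFAssignment] = None,
    labels: Optional[pd.Series] = None,
) -> AbundanceTable:
    """Sum features sharing a predicted host family into one PHF feature.

    Group labels come from ``assign``, or an explicit per-feature ``labels``
    series, or a ``phf`` feature-metadata column, in that order. Per-sample
    totals are conserved exactly. The output feature metadata carries the
    family label (``phf``) and the number of member features
    (``n_members``); for input tables with ``length_bp`` the member lengths
    are summed.
    """
    if labels is not None:
        labels = labels.loc[t.features].astype(str)
    else:
        labels = _phf_labels(t, assign)
    grouped = t.values.groupby(labels.values).sum()
    grouped.index.name = t.values.index.name
    meta = pd.DataFrame(index=grouped.index)
    meta["phf"] = meta.index
    meta["n_members"] = labels.value_counts().reindex(grouped.index)
    if t.feature_meta is not None and "length_bp" in t.feature_meta.columns:
        meta["length_bp"] = (
            t.feature_meta["length_bp"].groupby(labels.values).sum()
        )
    return AbundanceTable(grouped, meta, t.sample_meta)


def call_presence(
    cov: CoverageRecord | pd.DataFrame, lengths: Mapping[str, int] | pd.Series
) -> pd.DataFrame:
    """Length-stratified breadth-of-coverage presence calls.

    A vOTU is present in a sample when mapped reads cover at least 50% of a
    contig shorter than 5 kb, 30% of a contig of 5-20 kb, or 10% of a contig
    of 20 kb or longer.
    """
    breadth = cov.breadth if isinstance(cov, CoverageRecord) else cov
    lengths = pd.Series(lengths)
    missing = breadth.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"features with no length: {missing.tolist()}")
    lengths = lengths.loc[breadth.index].astype(float)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    threshold = pd.Series(
        np.select(
            [lengths < 5_000, lengths < 20_000],
            [0.50, 0.30],
            default=0.10,
        ),
        index=breadth.index,
    )
    return breadth.ge(threshold, axis=0)


def goods_coverage(counts: Sequence[float] | pd.Series) -> float:
    """Good's coverage estimator for one sample: 1 - singletons / total."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be >= 0")
    total = c.sum()
    if total <= 0:
        raise ValueError("Good's coverage is undefined for an empty sample")
    singletons = int((c == 1).sum())
    return 1.0 - singletons / total


def _per_kb_normalizer(values: pd.DataFrame, lengths: pd.Series) -> pd.Series:
    # reads per kilobase of contig, summed over features
    return values.div(lengths, axis=0).mul(1_000).sum(axis=0)


def filter_low_depth(
    t: AbundanceTable,
    lengths: Optional[pd.Series] = None,
    min_count: float = 1_500,
    normalizer: Callable[[pd.DataFrame, pd.Series], pd.Series] = _per_kb_normalizer,
) -> AbundanceTable:
    """Drop samples whose length-normalised viral read count falls below
    ``min_count`` (default 1,500).

    The default normaliser sums reads-per-kilobase over features; pass a
    different ``normalizer`` to change the definition.
    """
    if lengths is None:
        if t.feature_meta is None or "length_bp" not in t.feature_meta.columns:
            raise ValueError("need feature lengths (length_bp) to normalise depth")
        lengths = t.feature_meta["length_bp"]
    lengths = lengths.loc[t.features].astype(float)
    normalized = normalizer(t.values, lengths)
    keep = normalized[normalized >= min_count].index.tolist()
    return t.select_samples(keep)


def dereplicate(
    hits: Iterable[PairwiseHit],
    lengths: Mapping[str, int] | pd.Series,
    min_ani: float = 95.0,
    min_af: float = 85.0,
) -> dict[str, str]:
    """Greedy longest-first clustering of contigs into vOTUs.

    Contigs are visited by decreasing length (ties broken by id). Each
    unassigned contig becomes a representative; every other unassigned
    contig linked to it by a hit with ``ani >= min_ani`` and
    ``alignment_fraction >= min_af`` joins its cluster. Returns
    contig -> representative (representatives map to themselves).
    """
    lengths = pd.Series(lengths)
    neighbours: dict[str, set[str]] = {f: set() for f in lengths.index}
    for h in hits:
        for a, b in ((h.query_id, h.target_id), (h.target_id, h.query_id)):
            if a not in neighbours:
                raise ValueError(f"hit references unknown feature {a!r}")
        if h.query_id == h.target_id:
            continue
        if h.ani >= min_ani and h.alignment_fraction >= min_af:
            neighbours[h.query_id].add(h.target_id)
            neighbours[h.target_id].add(h.query_id)
    order = sorted(lengths.index, key=lambda f: (-lengths[f], f))
    rep: dict[str, str] = {}
    for f in order:
        if f in rep:
            continue
        rep[f] = f
        for g in sorted(neighbours[f]):
            if g not in rep:
                rep[g] = f
    return rep


def _presence_frame(t: AbundanceTable | pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    if isinstance(t, AbundanceTable):
        if t.sample_meta is None:
            raise ValueError("prevalence needs sample metadata with individual_id")
        return t.values > 0, t.sample_meta
    raise TypeError("pass an AbundanceTable, or use prevalence(presence, meta)")


def prevalence(
    t: AbundanceTable | pd.DataFrame,
    sample_meta: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Fraction of individuals in which each feature is present.

    A feature is present in an individual if it is present (value > 0, or
    True for a boolean presence matrix) in at least one of that individual's
    samples.
    """
    if isinstance(t, AbundanceTable):
        presence, sample_meta = _presence_frame(t)
    else:
        if sample_meta is None:
            raise ValueError("prevalence needs sample metadata with individual_id")
        presence = t.astype(bool)
    individuals = sample_meta.loc[presence.columns, "individual_id"]
    by_ind = presence.T.groupby(individuals.values).any()
    return by_ind.mean(axis=0).rename("prevalence")


def prevalent_features(prev: pd.Series, threshold: float = 0.5) -> pd.Index:
    """Features with prevalence strictly greater than ``threshold``."""
    return prev[prev > threshold].index


def prevalent_mass(
    t: AbundanceTable, prevalent: Iterable[str]
) -> tuple[pd.Series, float]:
    """Per-sample summed relative abundance of the prevalent features, and
    the cohort mean. ``t`` must be a relative abundance table."""
    keep = t.features.intersection(pd.Index(list(prevalent)))
    per_sample = t.values.loc[keep].sum(axis=0).rename("prevalent_mass")
    return per_sample, float(per_sample.mean()) if len(per_sample) else float("nan")


def amg_density(
    amg_counts: pd.Series, lengths_bp: pd.Series, groups: pd.Series
) -> pd.Series:
    """Auxiliary metabolic genes per megabase of assembled sequence, by group.

    For each group label: sum of AMG counts divided by the summed contig
    length in Mb. A group with zero total length is an error.
    """
    df = pd.DataFrame(
        {"amg": amg_counts, "len": lengths_bp, "group": groups}
    ).dropna(subset=["group"])
    sums = df.groupby("group")[["amg", "len"]].sum()
    if (sums["len"] <= 0).any():
        bad = sums.index[sums["len"] <= 0].tolist()
        raise ValueError(f"group(s) with zero assembled length: {bad}")
    return (sums["amg"] / (sums["len"] / 1e6)).rename("amg_per_mb")


def select_paired_individuals(sample_meta: pd.DataFrame) -> set[str]:
    """Individuals with at least one dysbiotic and one non-dysbiotic sample
    (the paired-design requirement for differential abundance)."""
    if "dysbiotic" not in sample_meta.columns:
        raise ValueError("sample metadata lacks 'dysbiotic'")
    meta = sample_meta.dropna(subset=["dysbiotic"])
    states = meta.groupby("individual_id")["dysbiotic"].agg(
        lambda s: {bool(v) for v in s}
    )
    return set(states[states.map(lambda st: st == {True, False})].index)


def filter_feature_meta(
    t: AbundanceTable, column: str, min_value: float
) -> AbundanceTable:
    """Keep features whose metadata ``column`` is >= ``min_value`` (e.g. the
    50% genome-completeness cut applied before dereplication)."""
    if t.feature_meta is None or column not in t.feature_meta.columns:
        raise ValueError(f"feature metadata lacks {column!r}")
    keep = t.feature_meta.index[t.feature_meta[column] >= min_value]
    keep = [f for f in t.features if f in set(keep)]
    return AbundanceTable(
        t.values.loc[keep],
        t.feature_meta.loc[keep],
        t.sample_meta,
    )
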