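"""Ecological distances, distance partitioning, longitudinal stability, and
the statistical comparisons between matched distance sets.

Bray-Curtis is computed on abundance vectors; UniFrac (unweighted and
normalised weighted) is computed against a rooted host tree by accumulating
per-branch descendant abundance. Weighted UniFrac here is the *normalised*
variant, so both metrics are bounded by 1. Virome stability is defined as
one minus the distance between consecutively collected samples of one
individual.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .io import AbundanceTable
from .taxonomy import Rank, NamespaceMap

__all__ = [
    "DistanceMatrix",
    "StabilitySeries",
    "MatchedComparisonReport",
    "bray_curtis",
    "unifrac",
    "distance_matrix",
    "partition_distances",
    "stability_series",
    "compare_metrics_matched",
    "correlate_phf_host",
    "prune_to_families",
]

METRICS = ("bray_curtis", "unifrac_unweighted", "unifrac_weighted")


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample distances with a metric label."""

    ids: tuple[str, ...]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("distance matrix has a non-zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        self.data = np.clip(d, 0.0, None)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.data[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=list(self.ids), columns=list(self.ids))

    def write(self, path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index_label="sample_id",
                               float_format="%.10g")

    @classmethod
    def read(cls, path, metric: str = "bray_curtis", sep: str = "\t"
             ) -> "DistanceMatrix":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return cls(tuple(df.index.astype(str)), df.to_numpy(float), metric)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity: sum|x - y| / sum(x + y), in [0, 1]."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if (xa < 0).any() or (ya < 0).any():
        raise ValueError("abundances must be >= 0")
    denom = (xa + ya).sum()
    if denom == 0:
        raise ValueError("Bray-Curtis is undefined for two empty samples")
    return float(np.abs(xa - ya).sum() / denom)


def _branch_profile(
    tree: TreeNode, features: Sequence[str], matrix: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-branch lengths and per-branch descendant abundance sums.

    ``matrix`` is features x samples. Returns ``(lengths, masses)`` where
    ``lengths`` has one entry per non-root branch and ``masses`` is
    branches x samples. Features must map onto tip names; tips without a
    feature contribute zero mass.
    """
    tip_names = {t.name for t in tree.tips()}
    missing = [f for f in features if f not in tip_names]
    if missing:
        raise ValueError(f"features without a tree tip: {missing}")
    row_of = {f: i for i, f in enumerate(features)}
    n_samples = matrix.shape[1]
    lengths = []
    masses = []
    # postorder accumulation: each node's mass = own tip mass + children's
    node_mass: dict[int, np.ndarray] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            i = row_of.get(node.name)
            m = matrix[i].astype(float) if i is not None else np.zeros(n_samples)
        else:
            m = np.zeros(n_samples)
            for child in node.children:
                m = m + node_mass[id(child)]
        node_mass[id(node)] = m
        if node.parent is not None:  # every non-root branch
            lengths.append(float(node.length or 0.0))
            masses.append(m)
    return np.asarray(lengths), np.asarray(masses)


def unifrac(
    tree: TreeNode,
    x: Mapping[str, float] | pd.Series,
    y: Mapping[str, float] | pd.Series,
    weighted: bool = False,
) -> float:
    """UniFrac distance between two abundance profiles on ``tree``.

    Unweighted: fraction of branch length leading to tips present in exactly
    one of the two profiles, over branch length leading to tips present in
    either. Weighted (normalised): sum over branches of
    ``L_b * |p_b(x) - p_b(y)|`` divided by ``L_b * (p_b(x) + p_b(y))``,
    where ``p_b`` is the fraction of a profile's total abundance descending
    from the branch. Both are in [0, 1].
    """
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    features = sorted(set(xs.index) | set(ys.index))
    mat = np.column_stack(
        [xs.reindex(features, fill_value=0.0).to_numpy(),
         ys.reindex(features, fill_value=0.0).to_numpy()]
    )
    lengths, masses = _branch_profile(tree, features, mat)
    mx, my = masses[:, 0], masses[:, 1]
    if weighted:
        totx, toty = mat[:, 0].sum(), mat[:, 1].sum()
        if totx == 0 or toty == 0:
            raise ValueError("weighted UniFrac is undefined for an empty sample")
        px, py = mx / totx, my / toty
        num = (lengths * np.abs(px - py)).sum()
        den = (lengths * (px + py)).sum()
    else:
        presx, presy = mx > 0, my > 0
        num = (lengths * (presx ^ presy)).sum()
        den = (lengths * (presx | presy)).sum()
    return float(num / den) if den > 0 else 0.0


def distance_matrix(
    t: AbundanceTable,
    metric: str = "bray_curtis",
    tree: Optional[TreeNode] = None,
) -> DistanceMatrix:
    """Pairwise distances between all samples of ``t`` under ``metric``."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = tuple(str(s) for s in t.samples)
    mat = t.values.to_numpy(float)
    if metric == "bray_curtis":
        if (mat.sum(axis=0) == 0).any():
            raise ValueError("Bray-Curtis is undefined for all-zero samples")
        d = squareform(pdist(mat.T, metric="braycurtis"))
        return DistanceMatrix(ids, d, metric)
    if tree is None:
        raise ValueError("UniFrac metrics require a host tree")
    features = [str(f) for f in t.features]
    lengths, masses = _branch_profile(tree, features, mat)
    totals = mat.sum(axis=0)
    n = len(ids)
    d = np.zeros((n, n))
    weighted = metric == "unifrac_weighted"
    if weighted and (totals == 0).any():
        raise ValueError("weighted UniFrac is undefined for all-zero samples")
    pres = masses > 0
    props = masses / np.where(totals == 0, 1.0, totals)[None, :]
    for i in range(n):
        for j in range(i + 1, n):
            if weighted:
                num = (lengths * np.abs(props[:, i] - props[:, j])).sum()
                den = (lengths * (props[:, i] + props[:, j])).sum()
            else:
                num = (lengths * (pres[:, i] ^ pres[:, j])).sum()
                den = (lengths * (pres[:, i] | pres[:, j])).sum()
            d[i, j] = d[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrix(ids, d, metric)


# ---------------------------------------------------------------------------
# partitioning and stability
# ---------------------------------------------------------------------------

def partition_distances(
    d: DistanceMatrix, sample_meta: pd.DataFrame
) -> dict[str, np.ndarray]:
    """Split all unordered sample pairs into intra-individual (same
    ``individual_id``) and inter-individual distances."""
    ind = sample_meta.loc[list(d.ids), "individual_id"]
    intra, inter = [], []
    for i, j in combinations(range(len(d.ids)), 2):
        value = d.data[i, j]
        if ind.iloc[i] == ind.iloc[j]:
            intra.append(value)
        else:
            inter.append(value)
    return {"intra": np.asarray(intra), "inter": np.asarray(inter)}


@dataclass
class StabilitySeries:
    """Per-individual stability (1 - distance) between consecutive samples.

    ``records`` has one row per consecutive pair, with columns
    ``individual_id``, ``sample_from``, ``sample_to``, ``time_from``,
    ``time_to``, ``distance``, ``stability``. Consecutive means adjacent in
    collection order, regardless of calendar gaps.
    """

    records: pd.DataFrame

    @property
    def values(self) -> np.ndarray:
        return self.records["stability"].to_numpy(float)

    def for_individual(self, individual_id: str) -> pd.DataFrame:
        return self.records[self.records["individual_id"] == individual_id]

    def write(self, path, sep: str = "\t") -> None:
        self.records.to_csv(path, sep=sep, index=False, float_format="%.10g")


def stability_series(
    d: DistanceMatrix, sample_meta: pd.DataFrame
) -> StabilitySeries:
    """Stability between consecutively collected samples of each individual.

    Individuals with fewer than two samples contribute nothing; a duplicate
    ``time_index`` within an individual is an error.
    """
    meta = sample_meta.loc[list(d.ids)]
    if "time_index" not in meta.columns:
        raise ValueError("sample metadata lacks time_index")
    rows = []
    for ind, group in meta.groupby("individual_id", sort=True):
        if group["time_index"].duplicated().any():
            raise ValueError(f"duplicate time_index for individual {ind!r}")
        ordered = group.sort_values("time_index")
        samples = list(ordered.index)
        times = list(ordered["time_index"])
        for k in range(len(samples) - 1):
            dist = d[samples[k], samples[k + 1]]
            rows.append(
                {
                    "individual_id": ind,
                    "sample_from": samples[k],
                    "sample_to": samples[k + 1],
                    "time_from": times[k],
                    "time_to": times[k + 1],
                    "distance": dist,
                    "stability": 1.0 - dist,
                }
            )
    return StabilitySeries(
        pd.DataFrame(
            rows,
            columns=[
                "individual_id", "sample_from", "sample_to",
                "time_from", "time_to", "distance", "stability",
            ],
        )
    )


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class MatchedComparisonReport:
    """Friedman omnibus test plus Bonferroni-adjusted pairwise Wilcoxon
    signed-rank tests over matched distance sets."""

    friedman_statistic: float
    friedman_p: float
    pairwise: pd.DataFrame  # group_a, group_b, statistic, p, p_adjusted, median_diff

    def significant_pairs(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.pairwise[self.pairwise["p_adjusted"] <= alpha]


def compare_metrics_matched(
    groups: Mapping[str, Sequence[float]]
) -> MatchedComparisonReport:
    """Compare >= 3 matched value sets (e.g. the same sample pairs measured
    under different metrics).

    Pairwise Wilcoxon p-values are two-sided and Bonferroni-adjusted by the
    number of pairwise tests actually performed, capped at 1. ``median_diff``
    is median(a - b), giving the effect direction.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 3:
        raise ValueError("need at least three matched groups")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise ValueError("matched groups must have equal lengths")
    if n == 0:
        raise ValueError("matched groups are empty")
    stacked = np.vstack(arrays)
    if np.allclose(stacked, stacked[0], atol=0):
        fr_stat, fr_p = 0.0, 1.0
    else:
        fr_stat, fr_p = stats.friedmanchisquare(*arrays)
    pairs = list(combinations(range(len(names)), 2))
    rows = []
    for i, j in pairs:
        diff = arrays[i] - arrays[j]
        if np.all(diff == 0):
            w_stat, p = 0.0, 1.0
        else:
            w_stat, p = stats.wilcoxon(arrays[i], arrays[j], zero_method="wilcox")
        rows.append(
            {
                "group_a": names[i],
                "group_b": names[j],
                "statistic": float(w_stat),
                "p": float(p),
                "p_adjusted": min(1.0, float(p) * len(pairs)),
                "median_diff": float(np.median(diff)),
            }
        )
    return MatchedComparisonReport(float(fr_stat), float(fr_p), pd.DataFrame(rows))


def correlate_phf_host(
    phf_abund: AbundanceTable,
    host_abund: AbundanceTable,
    nsmap: NamespaceMap,
    threshold: float = 0.6,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman correlation between each PHF and its host bacterial family.

    PHF names are translated through ``nsmap`` (family rank, fraction-mapping
    threshold 0.6 by default) to the host table's namespace; only mapped
    pairs with shared samples are tested. Pairs where either profile is
    constant have an undefined correlation and are flagged ``excluded``;
    Benjamini-Hochberg adjustment runs across the testable pairs.
    """
    shared = [s for s in phf_abund.samples if s in set(host_abund.samples)]
    if not shared:
        raise ValueError("no shared samples between PHF and host tables")
    rows = []
    for phf in phf_abund.features:
        mapped = nsmap.map_name(str(phf), Rank.FAMILY, threshold)
        if mapped is None or mapped not in set(map(str, host_abund.features)):
            continue
        x = phf_abund.values.loc[phf, shared].to_numpy(float)
        y = host_abund.values.loc[mapped, shared].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            rows.append(
                {"phf": str(phf), "host_family": mapped, "rho": np.nan,
                 "p": np.nan, "excluded": True}
            )
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append(
            {"phf": str(phf), "host_family": mapped, "rho": float(rho),
             "p": float(p), "excluded": False}
        )
    result = pd.DataFrame(
        rows, columns=["phf", "host_family", "rho", "p", "excluded"]
    )
    result["p_adjusted"] = np.nan
    testable = ~result["excluded"]
    if testable.any():
        result.loc[testable, "p_adjusted"] = stats.false_discovery_control(
            result.loc[testable, "p"].to_numpy()
        )
    result["significant"] = result["p_adjusted"] <= alpha
    return result


# ---------------------------------------------------------------------------
# tree plumbing
# ---------------------------------------------------------------------------

def prune_to_families(
    tree: TreeNode, tip_to_family: Mapping[str, str]
) -> TreeNode:
    """Reduce a genome-level host tree to one tip per family.

    The representative of each family is the first annotated tip encountered
    in a deterministic preorder traversal; the pruned tree's tips are renamed
    to the family names.
    """
    chosen: dict[str, str] = {}
    for node in tree.preorder(include_self=True):
        if node.is_tip():
            family = tip_to_family.get(node.name)
            if family is not None and family not in chosen:
                chosen[family] = node.name
    if not chosen:
        raise ValueError("no tree tip maps to any family")
    pruned = tree.shear(list(chosen.values()))
    rename = {tip_name: fam for fam, tip_name in chosen.items()}
    for tip in pruned.tips():
        tip.name = rename[tip.name]
    return pruned
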