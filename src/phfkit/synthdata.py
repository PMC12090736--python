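"""Synthetic virome cohorts with known ground truth.

Real gut virome cohorts combine two structural facts: communities are
individual-specific at the nucleotide (vOTU) level, yet family-level host
profiles are broadly shared across people. The generator reproduces exactly
that structure — individual family profiles drawn from a shared Dirichlet,
mostly-private vOTU pools within each family, first-order autoregressive
log-abundance dynamics over time, negative-binomial sequencing counts — and
attaches host-prediction and proximity-ligation tables derived from the true
lineages under configurable per-rank error rates.

Corrupted lineages stay internally consistent: an error planted at rank *r*
replaces the names at *r* and every deeper rank with those of a different
taxon that agrees with the truth above *r*. The marginal error probability
at each rank therefore equals the configured rate, and a wrong family
implies a wrong genus, exactly as real host-prediction errors behave.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import AbundanceTable, LinkageTable, PredictionTable
from .taxonomy import CONCORDANCE_RANKS, HostLineage, Rank

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "SyntheticCohort",
    "generate_cohort",
    "generate_host_tables",
    "plant_prevalence",
    "sample_depths",
]

_DEFAULT_PRED_ERROR = {
    Rank.PHYLUM: 0.02,
    Rank.CLASS: 0.03,
    Rank.ORDER: 0.04,
    Rank.FAMILY: 0.07,
    Rank.GENUS: 0.33,
}
_ZERO_ERROR = {r: 0.0 for r in CONCORDANCE_RANKS}


@dataclass
class CohortConfig:
    """Parameters of one synthetic cohort.

    Defaults emulate a year-long longitudinal cohort of ten healthy adults:
    14 collections per individual, a host-family space of 40 families with
    mostly individual-private vOTUs, 86.3% of contigs receiving any host
    prediction, and per-rank prediction error rising from 2% at phylum to
    33% at genus (host predictions degrade sharply below the family level).
    """

    n_individuals: int = 10
    samples_per_individual: int = 14
    n_families: int = 40
    votus_per_family_per_individual: int = 8
    shared_votu_fraction: float = 0.05
    family_profile_concentration: float = 50.0
    ar_persistence: float = 0.8
    lognormal_sigma: float = 1.0
    p_predicted: float = 0.863
    prediction_error: dict[Rank, float] = field(
        default_factory=lambda: dict(_DEFAULT_PRED_ERROR)
    )
    multi_prediction_rate: float = 0.3
    max_extra_predictions: int = 3
    hic_top_error: dict[Rank, float] = field(
        default_factory=lambda: dict(_ZERO_ERROR)
    )
    hic_multi_host_rate: float = 0.3
    max_extra_hosts: int = 3
    mean_depth: float = 50_000.0
    depth_dispersion: float = 0.3
    prophage_rate: float = 0.234
    amg_per_mb_prophage: float = 18.5
    amg_per_mb_other: float = 12.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1 or self.samples_per_individual < 1:
            raise ValueError("need at least one individual and one sample")
        if self.n_families < 2:
            raise ValueError("need at least two host families")
        for name in (
            "shared_votu_fraction", "p_predicted", "multi_prediction_rate",
            "hic_multi_host_rate", "prophage_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.ar_persistence < 1.0:
            raise ValueError("ar_persistence must lie in [0, 1)")
        if self.shared_votu_fraction > 0 and self.n_individuals < 2:
            raise ValueError(
                "a shared vOTU pool needs at least two individuals"
            )
        for err in (self.prediction_error, self.hic_top_error):
            rates = [err.get(r, 0.0) for r in CONCORDANCE_RANKS]
            if any(not 0.0 <= e <= 1.0 for e in rates):
                raise ValueError("error rates must lie in [0, 1]")
            if any(b < a - 1e-12 for a, b in zip(rates, rates[1:])):
                raise ValueError(
                    "error rates must be non-decreasing from phylum to genus"
                )


# ---------------------------------------------------------------------------
# taxonomy universe
# ---------------------------------------------------------------------------

_N_GENERA_PER_FAMILY = 3
_N_SPECIES_PER_GENUS = 2


def _split_chunks(n: int, k: int) -> list[list[int]]:
    """Split range(n) into k near-equal contiguous chunks."""
    edges = np.linspace(0, n, k + 1).astype(int)
    return [list(range(edges[i], edges[i + 1])) for i in range(k)]


class _Universe:
    """An internally consistent synthetic host taxonomy.

    Families are nested under orders, classes and phyla so that every family
    (in feasible configurations) has a sibling at each rank — required for
    planting rank-specific prediction errors.
    """

    def __init__(self, n_families: int):
        f = n_families
        n_phyla = max(2, f // 8) if f >= 4 else max(1, f // 2)
        n_phyla = min(n_phyla, max(1, f // 2))
        self.phylum_of = np.zeros(f, dtype=int)
        self.class_of = np.zeros(f, dtype=int)
        self.order_of = np.zeros(f, dtype=int)
        cls_counter = 0
        ord_counter = 0
        for p, chunk in enumerate(_split_chunks(f, n_phyla)):
            n_cls = 2 if len(chunk) >= 4 else 1
            for cc in _split_chunks(len(chunk), n_cls):
                n_ord = 2 if len(cc) >= 4 else 1
                for oc in _split_chunks(len(cc), n_ord):
                    for local in oc:
                        fam = chunk[cc[local]]
                        self.phylum_of[fam] = p
                        self.class_of[fam] = cls_counter
                        self.order_of[fam] = ord_counter
                    ord_counter += 1
                cls_counter += 1
        self.n_families = f
        self.family_names = [f"Fam{i:03d}" for i in range(f)]
        self.genus_names = [
            [f"{self.family_names[i]}-g{j}" for j in range(_N_GENERA_PER_FAMILY)]
            for i in range(f)
        ]

    def lineage(self, fam: int, genus: int, species: int) -> HostLineage:
        g = self.genus_names[fam][genus]
        return HostLineage(
            (
                "Bacteria",
                f"Phy{self.phylum_of[fam]:02d}",
                f"Cls{self.class_of[fam]:02d}",
                f"Ord{self.order_of[fam]:02d}",
                self.family_names[fam],
                g,
                f"{g} sp{species}",
            ),
            source_namespace="synthetic",
        )

    def siblings_at(self, fam: int, rank: Rank) -> np.ndarray:
        """Families whose lineage agrees with ``fam`` above ``rank`` but
        differs at ``rank`` (for family and shallower ranks)."""
        idx = np.arange(self.n_families)
        if rank == Rank.PHYLUM:
            return idx[self.phylum_of != self.phylum_of[fam]]
        if rank == Rank.CLASS:
            return idx[(self.phylum_of == self.phylum_of[fam])
                       & (self.class_of != self.class_of[fam])]
        if rank == Rank.ORDER:
            return idx[(self.class_of == self.class_of[fam])
                       & (self.order_of != self.order_of[fam])]
        if rank == Rank.FAMILY:
            return idx[(self.order_of == self.order_of[fam]) & (idx != fam)]
        raise ValueError(rank)

    def corrupt(
        self,
        rng: np.random.Generator,
        fam: int,
        genus: int,
        species: int,
        error: Mapping[Rank, float],
    ) -> tuple[HostLineage, Optional[Rank]]:
        """Return a possibly corrupted lineage and the shallowest wrong rank.

        The shallowest wrong rank ``R`` is drawn so that the marginal
        probability of being wrong at rank ``r`` equals ``error[r]`` (error
        rates must be non-decreasing with depth). Names at ``R`` and deeper
        are replaced by those of a sibling taxon; names above ``R`` are kept.
        """
        rates = [float(error.get(r, 0.0)) for r in CONCORDANCE_RANKS]
        u = rng.random()
        shallowest: Optional[Rank] = None
        prev = 0.0
        for r, e in zip(CONCORDANCE_RANKS, rates):
            if prev <= u < e:
                shallowest = r
                break
            prev = e
        if shallowest is None:
            return self.lineage(fam, genus, species), None
        if shallowest == Rank.GENUS:
            others = [g for g in range(_N_GENERA_PER_FAMILY) if g != genus]
            new_genus = int(rng.choice(others))
            new_species = int(rng.integers(_N_SPECIES_PER_GENUS))
            return self.lineage(fam, new_genus, new_species), Rank.GENUS
        candidates = self.siblings_at(fam, shallowest)
        if len(candidates) == 0:
            raise ValueError(
                f"infeasible config: no sibling taxon at rank {shallowest} "
                f"for family {self.family_names[fam]}; increase n_families"
            )
        new_fam = int(rng.choice(candidates))
        new_genus = int(rng.integers(_N_GENERA_PER_FAMILY))
        new_species = int(rng.integers(_N_SPECIES_PER_GENUS))
        return self.lineage(new_fam, new_genus, new_species), shallowest

    def tree(self, rng: np.random.Generator) -> TreeNode:
        """A rooted family-level host tree following the universe hierarchy,
        with uniform-random positive branch lengths."""
        root = TreeNode(name="root")
        phylum_nodes: dict[int, TreeNode] = {}
        class_nodes: dict[int, TreeNode] = {}
        order_nodes: dict[int, TreeNode] = {}
        for fam in range(self.n_families):
            p, c, o = (int(self.phylum_of[fam]), int(self.class_of[fam]),
                       int(self.order_of[fam]))
            if p not in phylum_nodes:
                node = TreeNode(name=f"Phy{p:02d}",
                                length=float(rng.uniform(0.1, 1.0)))
                root.append(node)
                phylum_nodes[p] = node
            if c not in class_nodes:
                node = TreeNode(name=f"Cls{c:02d}",
                                length=float(rng.uniform(0.1, 1.0)))
                phylum_nodes[p].append(node)
                class_nodes[c] = node
            if o not in order_nodes:
                node = TreeNode(name=f"Ord{o:02d}",
                                length=float(rng.uniform(0.1, 1.0)))
                class_nodes[c].append(node)
                order_nodes[o] = node
            tip = TreeNode(name=self.family_names[fam],
                           length=float(rng.uniform(0.1, 1.0)))
            order_nodes[o].append(tip)
        return root


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    lineages: dict[str, HostLineage]
    predicted_contigs: set[str]
    expected_concordance: dict[Rank, float]
    family_profiles: pd.DataFrame  # individuals x families
    config: CohortConfig

    def write(self, path, sep: str = "\t") -> None:
        rows = [
            {"contig_id": c, "lineage": l.serialize(),
             "predicted": c in self.predicted_contigs}
            for c, l in self.lineages.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


@dataclass
class SyntheticCohort:
    predictions: PredictionTable
    linkages: LinkageTable
    abundance: AbundanceTable
    tree: TreeNode
    truth: GroundTruth


# ---------------------------------------------------------------------------
# host-assignment tables
# ---------------------------------------------------------------------------

def _confidence(depth_of_error: int, rng: np.random.Generator,
                primary: bool) -> float:
    # only the ordering matters downstream; primaries always outrank extras
    quality = 1.0 - depth_of_error / 6.0
    if primary:
        return 95.0 + 4.0 * quality + float(rng.uniform(0, 1))
    return 60.0 + 25.0 * quality + float(rng.uniform(0, 5))


def _error_depth(shallowest: Optional[Rank]) -> int:
    return 0 if shallowest is None else len(Rank) - int(shallowest)


def generate_host_tables(
    cfg: CohortConfig,
    n_contigs: int,
    rng: Optional[np.random.Generator] = None,
    universe: Optional[_Universe] = None,
    contig_taxa: Optional[Sequence[tuple[str, int, int, int]]] = None,
) -> tuple[PredictionTable, LinkageTable, GroundTruth]:
    """Prediction and linkage tables for ``n_contigs`` contigs.

    Every contig receives a top proximity-ligation link (corrupted at the
    ``hic_top_error`` rates) and, at rate ``hic_multi_host_rate``, extra
    lower-ranked links to random taxa. A fraction ``p_predicted`` of contigs
    receive predictions: a primary one corrupted at ``prediction_error``
    rates plus, at rate ``multi_prediction_rate``, extra lower-confidence
    predictions corrupted independently.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if universe is None:
        universe = _Universe(cfg.n_families)
    if contig_taxa is None:
        contig_taxa = [
            (
                f"contig{i:05d}",
                int(rng.integers(cfg.n_families)),
                int(rng.integers(_N_GENERA_PER_FAMILY)),
                int(rng.integers(_N_SPECIES_PER_GENUS)),
            )
            for i in range(n_contigs)
        ]

    pred_rows = []
    link_rows = []
    lineages: dict[str, HostLineage] = {}
    predicted: set[str] = set()
    for contig, fam, gen, spec in contig_taxa:
        truth = universe.lineage(fam, gen, spec)
        lineages[contig] = truth

        top_link, _ = universe.corrupt(rng, fam, gen, spec, cfg.hic_top_error)
        link_rows.append({"contig_id": contig, "lineage": top_link,
                          "link_rank": 1})
        if rng.random() < cfg.hic_multi_host_rate:
            n_extra = int(rng.integers(1, cfg.max_extra_hosts + 1))
            for k in range(n_extra):
                other = int(rng.integers(cfg.n_families))
                lin = universe.lineage(
                    other,
                    int(rng.integers(_N_GENERA_PER_FAMILY)),
                    int(rng.integers(_N_SPECIES_PER_GENUS)),
                )
                link_rows.append({"contig_id": contig, "lineage": lin,
                                  "link_rank": 2 + k})

        if rng.random() < cfg.p_predicted:
            predicted.add(contig)
            lin, shallowest = universe.corrupt(
                rng, fam, gen, spec, cfg.prediction_error
            )
            pred_rows.append({
                "contig_id": contig, "lineage": lin,
                "confidence": _confidence(_error_depth(shallowest), rng, True),
            })
            if rng.random() < cfg.multi_prediction_rate:
                n_extra = int(rng.integers(1, cfg.max_extra_predictions + 1))
                for _ in range(n_extra):
                    lin, shallowest = universe.corrupt(
                        rng, fam, gen, spec, cfg.prediction_error
                    )
                    pred_rows.append({
                        "contig_id": contig, "lineage": lin,
                        "confidence": _confidence(
                            _error_depth(shallowest), rng, False),
                    })

    truth = GroundTruth(
        lineages=lineages,
        predicted_contigs=predicted,
        expected_concordance={
            r: 1.0 - cfg.prediction_error.get(r, 0.0) for r in CONCORDANCE_RANKS
        },
        family_profiles=pd.DataFrame(),
        config=cfg,
    )
    pred = PredictionTable(pd.DataFrame(
        pred_rows, columns=["contig_id", "lineage", "confidence"]))
    link = LinkageTable(pd.DataFrame(
        link_rows, columns=["contig_id", "lineage", "link_rank"]))
    return pred, link, truth


# ---------------------------------------------------------------------------
# full cohort
# ---------------------------------------------------------------------------

def generate_cohort(cfg: CohortConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort, reproducible from ``cfg.seed``.

    Returns prediction and linkage tables, a vOTU x sample count matrix with
    feature and sample metadata, a family-level host tree, and the ground
    truth (true lineages, per-individual family profiles, expected per-rank
    concordance).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    universe = _Universe(cfg.n_families)
    F = cfg.n_families
    K = cfg.votus_per_family_per_individual
    individuals = [f"ind{i:02d}" for i in range(cfg.n_individuals)]

    # shared vOTU pool: one candidate pool per family
    shared_pool: dict[int, list[str]] = {}
    contig_taxa: list[tuple[str, int, int, int]] = []
    counter = 0

    def _new_contig(fam: int) -> str:
        nonlocal counter
        cid = f"votu{counter:05d}"
        counter += 1
        contig_taxa.append((
            cid, fam,
            int(rng.integers(_N_GENERA_PER_FAMILY)),
            int(rng.integers(_N_SPECIES_PER_GENUS)),
        ))
        return cid

    for fam in range(F):
        shared_pool[fam] = [_new_contig(fam) for _ in range(K)]

    membership: dict[str, dict[int, list[str]]] = {}
    for ind in individuals:
        fam_votus: dict[int, list[str]] = {}
        for fam in range(F):
            votus = []
            for _ in range(K):
                if rng.random() < cfg.shared_votu_fraction:
                    votus.append(shared_pool[fam][int(rng.integers(K))])
                else:
                    votus.append(_new_contig(fam))
            fam_votus[fam] = sorted(set(votus))
        membership[ind] = fam_votus

    all_contigs = [c for c, *_ in contig_taxa]
    fam_of = {c: fam for c, fam, _, _ in contig_taxa}

    # family profiles: individuals resemble each other at family level
    base = rng.dirichlet(np.full(F, 2.0))
    profiles = np.vstack([
        rng.dirichlet(cfg.family_profile_concentration * base + 1e-3)
        for _ in individuals
    ])
    family_profiles = pd.DataFrame(
        profiles, index=individuals, columns=universe.family_names
    )

    # abundance dynamics: AR(1) on log abundance around a per-vOTU baseline
    T = cfg.samples_per_individual
    phi = cfg.ar_persistence
    sigma = cfg.lognormal_sigma
    sample_ids: list[str] = []
    sample_meta_rows = []
    columns: dict[str, np.ndarray] = {}
    contig_index = {c: i for i, c in enumerate(all_contigs)}
    for i_ind, ind in enumerate(individuals):
        votus: list[str] = []
        weights: list[float] = []
        for fam in range(F):
            members = membership[ind][fam]
            split = rng.dirichlet(np.ones(len(members)))
            for m, w in zip(members, split):
                votus.append(m)
                weights.append(profiles[i_ind, fam] * w)
        mu = np.log(np.asarray(weights) + 1e-300)
        z = rng.normal(0.0, sigma, size=len(votus))
        for t in range(T):
            if t > 0:
                z = phi * z + rng.normal(
                    0.0, sigma * np.sqrt(1.0 - phi ** 2), size=len(votus)
                )
            rel = np.exp(mu + z)
            rel = rel / rel.sum()
            mean_counts = cfg.mean_depth * rel
            lam = rng.gamma(
                1.0 / cfg.depth_dispersion, mean_counts * cfg.depth_dispersion
            )
            counts = rng.poisson(lam)
            col = np.zeros(len(all_contigs))
            col[[contig_index[v] for v in votus]] = counts
            sid = f"{ind}_t{t:02d}"
            sample_ids.append(sid)
            sample_meta_rows.append(
                {"sample_id": sid, "individual_id": ind, "time_index": t}
            )
            columns[sid] = col

    values = pd.DataFrame(columns, index=all_contigs)
    lengths = np.clip(
        rng.lognormal(np.log(10_000), 0.6, size=len(all_contigs)),
        1_500, 500_000,
    ).astype(int)
    prophage = rng.random(len(all_contigs)) < cfg.prophage_rate
    amg_rate = np.where(
        prophage, cfg.amg_per_mb_prophage, cfg.amg_per_mb_other
    )
    amg_count = rng.poisson(amg_rate * lengths / 1e6)
    feature_meta = pd.DataFrame(
        {
            "length_bp": lengths,
            "true_family": [universe.family_names[fam_of[c]] for c in all_contigs],
            "prophage": prophage,
            "amg_count": amg_count,
        },
        index=pd.Index(all_contigs, name="feature_id"),
    )
    sample_meta = pd.DataFrame(sample_meta_rows).set_index("sample_id")
    abundance = AbundanceTable(values, feature_meta, sample_meta)

    pred, link, truth = generate_host_tables(
        cfg, len(all_contigs), rng=rng, universe=universe,
        contig_taxa=contig_taxa,
    )
    truth.family_profiles = family_profiles
    tree = universe.tree(rng)
    return SyntheticCohort(pred, link, abundance, tree, truth)


# ---------------------------------------------------------------------------
# planted prevalence and depth models
# ---------------------------------------------------------------------------

def plant_prevalence(
    cfg: CohortConfig, k_prevalent: int
) -> tuple[AbundanceTable, list[str]]:
    """A family-level table where exactly ``k_prevalent`` features occur in
    more than half of the individuals and the rest in at most half.

    Returns the table (counts, with sample metadata) and the planted feature
    names.
    """
    cfg.validate()
    if not 0 <= k_prevalent <= cfg.n_families:
        raise ValueError("k_prevalent must lie in [0, n_families]")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_individuals
    half = n // 2
    features = [f"Fam{i:03d}" for i in range(cfg.n_families)]
    planted = sorted(
        rng.choice(cfg.n_families, size=k_prevalent, replace=False).tolist()
    )
    planted_names = [features[i] for i in planted]
    individuals = [f"ind{i:02d}" for i in range(n)]
    samples = [
        f"{ind}_t{t:02d}"
        for ind in individuals
        for t in range(cfg.samples_per_individual)
    ]
    sample_meta = pd.DataFrame(
        {
            "individual_id": [s.split("_t")[0] for s in samples],
            "time_index": [int(s.split("_t")[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    spi = cfg.samples_per_individual
    mat = np.zeros((cfg.n_families, len(samples)))
    planted_set = set(planted)
    for i in range(cfg.n_families):
        if i in planted_set:
            m = int(rng.integers(half + 1, n + 1))
        else:
            m = int(rng.integers(0, half + 1))
        chosen = rng.choice(n, size=m, replace=False)
        for ci in chosen:
            n_hits = int(rng.integers(1, spi + 1))
            hit_ts = rng.choice(spi, size=n_hits, replace=False)
            cols = ci * spi + hit_ts
            mat[i, cols] = rng.integers(1, 100, size=n_hits)
    values = pd.DataFrame(mat, index=features, columns=samples)
    table = AbundanceTable(values, None, sample_meta)
    return table, planted_names


def sample_depths(
    n_samples: int,
    rng: np.random.Generator,
    below_fraction: float = 0.315,
    threshold: float = 1_500.0,
    sigma: float = 1.0,
) -> np.ndarray:
    """Log-normal per-sample sequencing depths calibrated so that a fraction
    ``below_fraction`` of samples falls below ``threshold`` in expectation —
    the depth regime under which roughly two-thirds of a cohort survives a
    minimum-count filter."""
    from scipy.stats import norm

    if not 0 < below_fraction < 1:
        raise ValueError("below_fraction must lie in (0, 1)")
    mu = np.log(threshold) - sigma * norm.ppf(below_fraction)
    return rng.lognormal(mu, sigma, size=n_samples)
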