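"""Independent brute-force oracles used only by the test suite.

These deliberately re-derive results from first principles — naive loops and
exhaustive enumeration — and share no code with the library paths they
check.
"""

from __future__ import annotations

import numpy as np

from phfkit.taxonomy import CONCORDANCE_RANKS, HostLineage, Rank


def brute_force_concordance(
    predictions: dict[str, list[tuple[HostLineage, float]]],
    links: dict[str, list[tuple[HostLineage, int]]],
) -> dict[tuple[Rank, str], tuple[int, int]]:
    """Enumerate every (contig, rank, mode) tuple naively.

    ``predictions`` maps contig -> [(lineage, confidence)] in any order;
    ``links`` maps contig -> [(lineage, link_rank)] in any order. Returns
    (rank, mode) -> (n_concordant, n_total) over the shared contigs, using
    the same tie-break convention as the library (highest confidence, then
    lexicographically smallest serialised lineage) re-implemented here from
    scratch.
    """
    shared = sorted(set(predictions) & set(links))
    out: dict[tuple[Rank, str], tuple[int, int]] = {}
    for rank in CONCORDANCE_RANKS:
        for mode in ("strict", "top_vs_any", "any_vs_any"):
            n_conc = 0
            for contig in shared:
                preds = predictions[contig]
                best_pred = min(
                    preds, key=lambda pl: (-pl[1], pl[0].serialize())
                )[0]
                hics = sorted(links[contig], key=lambda lr: lr[1])
                top_hic = hics[0][0]

                def eq(a: HostLineage, b: HostLineage) -> bool:
                    na, nb = a.name_at(rank), b.name_at(rank)
                    return na != "" and na == nb

                if mode == "strict":
                    hit = eq(best_pred, top_hic)
                elif mode == "top_vs_any":
                    hit = any(eq(best_pred, h) for h, _ in hics)
                else:
                    hit = any(eq(p, h) for p, _ in preds for h, _ in hics)
                n_conc += int(hit)
            out[(rank, mode)] = (n_conc, len(shared))
    return out


def enumerate_branches(tree) -> list[tuple[float, frozenset[str]]]:
    """(branch length, descendant tip names) for every non-root branch,
    found by walking up from each node independently."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = frozenset(t.name for t in ([node] if node.is_tip() else node.tips()))
        out.append((float(node.length or 0.0), tips))
    return out


def unifrac_oracle(tree, x: dict[str, float], y: dict[str, float],
                   weighted: bool) -> float:
    """UniFrac by explicit branch enumeration with scalar python loops."""
    branches = enumerate_branches(tree)
    if weighted:
        tx = sum(x.values())
        ty = sum(y.values())
        num = 0.0
        den = 0.0
        for length, tips in branches:
            px = sum(x.get(t, 0.0) for t in tips) / tx
            py = sum(y.get(t, 0.0) for t in tips) / ty
            num += length * abs(px - py)
            den += length * (px + py)
        return num / den if den > 0 else 0.0
    num = 0.0
    den = 0.0
    for length, tips in branches:
        in_x = any(x.get(t, 0.0) > 0 for t in tips)
        in_y = any(y.get(t, 0.0) > 0 for t in tips)
        if in_x != in_y:
            num += length
        if in_x or in_y:
            den += length
    return num / den if den > 0 else 0.0


def random_tree(rng: np.random.Generator, n_tips: int):
    """A random rooted binary tree with uniform branch lengths in (0, 1]."""
    from skbio import TreeNode

    nodes = [
        TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0)))
        for i in range(n_tips)
    ]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.append(nodes[i])
        parent.append(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = TreeNode(name="root")
    for n in nodes:
        root.append(n)
    return root
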