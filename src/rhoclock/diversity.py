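"""Classic diversity statistics on mutation-annotated trees.

These are the comparison statistics: classic rho (mean root-to-tip mutation
count), the mean pairwise difference pi, the number of segregating sites S,
and the per-period rho values whose sum is the modified rho.  The tree is
taken at face value under a no-homoplasy model — every branch mutation is a
distinct site — so pairwise differences are path sums through the MRCA.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

from .tree import CoalescentPeriodTable, MutationTree, TreeValidationError

__all__ = [
    "DiversityStats",
    "classic_rho",
    "pairwise_pi",
    "per_period_rho",
    "modified_rho",
    "segregating_sites",
    "diversity_stats",
]


def classic_rho(tree: MutationTree) -> Fraction:
    """Mean number of mutations separating each tip from the root type."""
    paths = tree.tip_path_mutations()
    return sum(paths.values(), Fraction(0)) / len(paths)


def pairwise_pi(
    tree: MutationTree, sequence_length: int | None = None
) -> Fraction:
    """Mean pairwise difference over all unordered tip pairs.

    Per-molecule by default; dividing by ``sequence_length`` gives the
    per-site value.  On a star tree pi equals exactly twice the classic rho
    (each pairwise path counts both tips' private mutations once).
    """
    if tree.n_tips < 2:
        raise TreeValidationError("pi needs at least 2 tips")
    # depth of every node from root, then pairwise distance through the MRCA:
    # d(u, v) = depth(u) + depth(v) - 2 depth(mrca)
    depth: dict[int, Fraction] = {}
    parent: dict[int, int] = {}
    nodes = {}

    def walk(node, acc: Fraction) -> None:
        acc = acc + (node.mutations or Fraction(0))
        depth[id(node)] = acc
        nodes[id(node)] = node
        for child in node.children:
            parent[id(child)] = id(node)
            walk(child, acc)

    walk(tree.root, Fraction(0))

    def ancestors(nid: int) -> list[int]:
        out = [nid]
        while nid in parent:
            nid = parent[nid]
            out.append(nid)
        return out

    tips = tree.root.tips()
    total = Fraction(0)
    for a, b in combinations(tips, 2):
        anc_a = ancestors(id(a))
        anc_b = set(ancestors(id(b)))
        mrca = next(nid for nid in anc_a if nid in anc_b)
        total += depth[id(a)] + depth[id(b)] - 2 * depth[mrca]
    n_pairs = len(tips) * (len(tips) - 1) // 2
    pi = total / n_pairs
    if sequence_length is not None:
        pi = pi / sequence_length
    return pi


def per_period_rho(table: CoalescentPeriodTable) -> dict[int, Fraction]:
    """Per-period rho values: ``rho_i = gamma_i / i`` for every period."""
    return {row.index: row.rho() for row in table.rows}


def modified_rho(table: CoalescentPeriodTable) -> Fraction:
    """The modified rho: sum of the per-period rho values."""
    return sum((row.rho() for row in table.rows), Fraction(0))


def segregating_sites(tree: MutationTree) -> Fraction:
    """Number of segregating sites under the no-homoplasy model.

    A mutation segregates when its descendant-tip set is a proper nonempty
    subset of the sample, i.e. it lies on a branch subtending between 1 and
    n-1 tips.  With integer branch counts the result is an integer.
    """
    n = tree.n_tips
    total = Fraction(0)
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        k = 1 if node.is_tip else len(node.tips())
        if 1 <= k <= n - 1:
            total += node.mutations  # type: ignore[operator]
    return total


@dataclass(frozen=True)
class DiversityStats:
    """Bundle of the classic diversity estimators for one tree."""

    n: int
    rho_classic: Fraction
    pi: Fraction
    s_per_sequence: Fraction
    pi_per_site: float | None = None
    s_per_site: float | None = None

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rho_classic": float(self.rho_classic),
            "pi": float(self.pi),
            "segregating_sites": float(self.s_per_sequence),
            "pi_per_site": self.pi_per_site,
            "s_per_site": self.s_per_site,
        }


def diversity_stats(
    tree: MutationTree, sequence_length: int | None = None
) -> DiversityStats:
    """Compute rho, pi and S for a tree (per-site variants when a length is given)."""
    pi = pairwise_pi(tree)
    s = segregating_sites(tree)
    return DiversityStats(
        n=tree.n_tips,
        rho_classic=classic_rho(tree),
        pi=pi,
        s_per_sequence=s,
        pi_per_site=float(pi) / sequence_length if sequence_length else None,
        s_per_site=float(s) / sequence_length if sequence_length else None,
    )
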