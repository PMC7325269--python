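"""Mutation-annotated rooted trees and their coalescent-period decomposition.

A :class:`MutationTree` is a rooted tree whose tips are sampled sequences and
whose branch lengths are *mutation counts* on the whole molecule (non-negative,
kept as exact :class:`fractions.Fraction` values so that apportionment of
branches spanning several coalescent periods conserves mutations exactly).

The central intermediate for age estimation is the
:class:`CoalescentPeriodTable`: one row per coalescent period, indexed by the
number ``i`` of ancestral lineages extant during the period, carrying the total
number of mutations ``gamma_i`` accumulated across all lineages during it.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import dendropy

__all__ = [
    "MutationTree",
    "TreeNode",
    "CoalescentPeriodTable",
    "PeriodRow",
    "IsolateAssignment",
    "TreeValidationError",
    "NewickParseError",
    "read_newick_mutation_tree",
    "decompose_into_periods",
    "apportion_spanning_mutations",
    "read_period_table",
    "write_period_table",
]

logger = logging.getLogger(__name__)

#: Plausibility window for mutations on a single-period tip branch.  Under a
#: Poisson mutation process at the whole-mtDNA germline rate, 0-5 mutations per
#: lineage within one coalescent period is the plausible range; exceeding it is
#: reported as a warning, never enforced.
TIP_PERIOD_MUTATION_WINDOW = 5


class TreeValidationError(ValueError):
    """A tree (or period table) violates a structural invariant."""


class NewickParseError(ValueError):
    """Malformed Newick input; the message names the offending position."""


def _as_fraction(value) -> Fraction:
    """Convert a branch length to an exact Fraction.

    Floats are converted through ``repr`` so that the decimal token written in
    the Newick source (e.g. ``1.5``) is recovered exactly rather than its
    binary expansion.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    return Fraction(str(value))


@dataclass
class TreeNode:
    """A node of a :class:`MutationTree`.

    ``mutations`` is the mutation count on the branch to the parent; it is
    ``None`` exactly for the root.
    """

    label: str | None = None
    mutations: Fraction | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_tip]


class MutationTree:
    """Rooted tree with non-negative mutation counts on every non-root branch."""

    def __init__(self, root: TreeNode, validate: bool = True) -> None:
        self.root = root
        self._collapse_unifurcations()
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    def _collapse_unifurcations(self) -> None:
        # a unifurcating root is replaced by its child (root branch length is
        # meaningless and dropped with a warning if present)
        while len(self.root.children) == 1:
            child = self.root.children[0]
            if child.mutations:
                warnings.warn(
                    "collapsing unifurcating root: branch above the new root "
                    f"carried {child.mutations} mutations, which are ignored"
                )
            child.parent = None
            child.mutations = None
            self.root = child
        for node in list(self.root.preorder()):
            for i, child in enumerate(list(node.children)):
                while len(child.children) == 1:
                    grand = child.children[0]
                    grand.mutations = (grand.mutations or Fraction(0)) + (
                        child.mutations or Fraction(0)
                    )
                    grand.parent = node
                    node.children[i] = grand
                    child = grand

    def validate(self) -> None:
        seen_labels: set[str] = set()
        for node in self.root.preorder():
            if node is self.root:
                if node.parent is not None:
                    raise TreeValidationError("root must not have a parent")
            else:
                if node.parent is None:
                    raise TreeValidationError("non-root node lacks a parent")
                if node.mutations is None:
                    raise TreeValidationError(
                        "missing branch length (mutation count) on branch to "
                        f"{node.label or 'an internal node'}"
                    )
                if node.mutations < 0:
                    raise TreeValidationError(
                        f"negative mutation count {node.mutations} on branch to "
                        f"{node.label or 'an internal node'}"
                    )
            if node.is_tip:
                if not node.label:
                    raise TreeValidationError("every tip must carry a label")
                if node.label in seen_labels:
                    raise TreeValidationError(f"duplicate tip label {node.label!r}")
                seen_labels.add(node.label)
        if self.n_tips < 2:
            raise TreeValidationError("a mutation tree needs at least 2 tips")

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.root.tips())

    def tip_labels(self) -> list[str]:
        return [t.label for t in self.root.tips()]  # type: ignore[misc]

    def total_mutations(self) -> Fraction:
        return sum(
            (n.mutations for n in self.root.preorder() if n is not self.root),
            Fraction(0),
        )

    def branch_mutations(self) -> dict[str, Fraction]:
        """Mutation count per branch, keyed by tip label or by the sorted
        descendant-tip set (``"a|b"``) for internal branches."""
        out: dict[str, Fraction] = {}
        for node in self.root.preorder():
            if node is self.root:
                continue
            key = node.label if node.is_tip else "|".join(
                sorted(t.label for t in node.tips())  # type: ignore[misc]
            )
            out[key] = node.mutations  # type: ignore[assignment]
        return out

    def tip_path_mutations(self) -> dict[str, Fraction]:
        """Root-to-tip mutation count for every tip."""
        out: dict[str, Fraction] = {}

        def walk(node: TreeNode, acc: Fraction) -> None:
            acc = acc + (node.mutations or Fraction(0))
            if node.is_tip:
                out[node.label] = acc  # type: ignore[index]
            for child in node.children:
                walk(child, acc)

        walk(self.root, Fraction(0))
        return out

    # -- Newick I/O --------------------------------------------------------

    @classmethod
    def from_newick(cls, source: str | Path) -> "MutationTree":
        return read_newick_mutation_tree(source)

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node.mutations is not None:
                m = node.mutations
                core += f":{int(m)}" if m.denominator == 1 else f":{float(m)!r}"
            return core

        return fmt(self.root) + ";"


def read_newick_mutation_tree(source: str | Path) -> MutationTree:
    """Read a single Newick tree whose branch lengths are mutation counts.

    Parameters
    ----------
    source
        A path to a Newick file, or a Newick string itself (detected by the
        presence of ``(`` / ``;``).

    Missing branch lengths are an error (a silently-zero branch would corrupt
    the period decomposition); a branch length on the root, if present, is
    ignored with a warning.
    """
    if isinstance(source, Path) or (
        "(" not in str(source) and ";" not in str(source)
    ):
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no such tree file: {path}")
        text = path.read_text()
    else:
        text = str(source)

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            terminating_semicolon_required=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None:
            pos = f" at line {line}" + (f", column {col}" if col is not None else "")
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label=label)
        if dnode.edge.length is not None:
            node.mutations = _as_fraction(dnode.edge.length)
        for dchild in dnode.child_nodes():
            child = convert(dchild)
            child.parent = node
            node.children.append(child)
        return node

    root = convert(dtree.seed_node)
    if root.mutations is not None:
        warnings.warn(
            f"ignoring branch length {root.mutations} on the root (the root has "
            "no parent branch)"
        )
        root.mutations = None
    # dendropy leaves edge.length None when absent; flag that explicitly
    for node in root.preorder():
        if node is not root and node.mutations is None:
            raise TreeValidationError(
                "missing branch length (mutation count) on branch to "
                f"{node.label or 'an internal node'}; every non-root branch "
                "must state its mutation count explicitly"
            )
    return MutationTree(root)


# ---------------------------------------------------------------------------
# coalescent-period decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeriodRow:
    """One coalescent period: ``index`` lineages extant, ``gamma`` mutations."""

    index: int
    gamma: Fraction
    note: str = "direct"

    def rho(self) -> Fraction:
        return self.gamma / self.index


@dataclass(frozen=True)
class IsolateAssignment:
    """Apportionment of one spanning ("isolate") branch across periods."""

    branch: str
    allocations: tuple[tuple[int, Fraction], ...]

    @property
    def total(self) -> Fraction:
        return sum((a for _, a in self.allocations), Fraction(0))


class CoalescentPeriodTable:
    """Ordered coalescent periods, ascending in lineage count.

    The first row is the root-adjacent period (smallest ``i``, typically 2)
    and the last row the tip period (``i = n``).  ``sum(gamma)`` equals the
    total branch mutations of the source tree exactly.
    """

    def __init__(self, rows: Sequence[PeriodRow]) -> None:
        rows = sorted(rows, key=lambda r: r.index)
        indices = [r.index for r in rows]
        if len(set(indices)) != len(indices):
            raise TreeValidationError("duplicate period index in table")
        for r in rows:
            if r.index < 2:
                raise TreeValidationError(f"period index {r.index} < 2")
            if r.gamma < 0:
                raise TreeValidationError(f"negative mutation count in period {r.index}")
        if not rows:
            raise TreeValidationError("a period table needs at least one row")
        self.rows: tuple[PeriodRow, ...] = tuple(rows)

    @property
    def n(self) -> int:
        """Sample size: the largest realized lineage count (tip period)."""
        return self.rows[-1].index

    def gamma(self) -> dict[int, Fraction]:
        return {r.index: r.gamma for r in self.rows}

    def total_mutations(self) -> Fraction:
        return sum((r.gamma for r in self.rows), Fraction(0))

    def __iter__(self) -> Iterator[PeriodRow]:
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoalescentPeriodTable):
            return NotImplemented
        return [(r.index, r.gamma) for r in self.rows] == [
            (r.index, r.gamma) for r in other.rows
        ]

    def __repr__(self) -> str:
        cells = ", ".join(f"i={r.index}: {r.gamma}" for r in self.rows)
        return f"CoalescentPeriodTable({cells})"

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "period": [r.index for r in self.rows],
                "lineages": [r.index for r in self.rows],
                "mutations": [float(r.gamma) for r in self.rows],
                "note": [r.note for r in self.rows],
            }
        )


def apportion_spanning_mutations(
    branch_mutations: Fraction | int,
    spanned_periods: Sequence[int],
    internode_gamma: Mapping[int, Fraction | int],
    branch: str = "",
) -> IsolateAssignment:
    """Distribute an isolate branch's mutations over the periods it spans.

    The weight of each spanned period is the mutation total of the *internode*
    branches confined to that single period; the allocation to period ``p`` is
    ``branch_mutations * internode_gamma[p] / sum(internode_gamma)``, an exact
    rational.  When all internode weights are zero the mutations are spread
    uniformly (conservation is never violated).
    """
    if not spanned_periods:
        raise TreeValidationError("spanned_periods must be non-empty")
    m = _as_fraction(branch_mutations)
    weights = [_as_fraction(internode_gamma.get(p, 0)) for p in spanned_periods]
    if any(w < 0 for w in weights):
        raise TreeValidationError("internode mutation totals must be >= 0")
    total = sum(weights, Fraction(0))
    if total == 0:
        logger.info(
            "isolate branch %s: all internode mutation totals are zero over "
            "periods %s; falling back to uniform apportionment",
            branch or "<unnamed>",
            list(spanned_periods),
        )
        k = len(spanned_periods)
        allocations = tuple((p, m / k) for p in spanned_periods)
    else:
        allocations = tuple(
            (p, m * w / total) for p, w in zip(spanned_periods, weights)
        )
    assignment = IsolateAssignment(branch=branch, allocations=allocations)
    assert assignment.total == m
    return assignment


def _order_coalescent_events(tree: MutationTree) -> list[TreeNode]:
    """Totally order internal nodes from most recent to most ancient.

    A cladogram with mutation counts gives only a partial order of coalescent
    events (a parent cannot coalesce before its child).  Within that
    constraint, nodes are ranked by (1) mean mutation-count distance to their
    descendant tips, ascending, (2) number of descendant tips, ascending,
    (3) lexicographically smallest descendant tip label — a deterministic
    convention, invariant to the child order of the input Newick.
    """
    internal = [n for n in tree.root.preorder() if not n.is_tip]
    keys: dict[int, tuple] = {}
    for node in internal:
        dists = []

        def collect(child: TreeNode, acc: Fraction) -> None:
            acc = acc + (child.mutations or Fraction(0))
            if child.is_tip:
                dists.append(acc)
            for g in child.children:
                collect(g, acc)

        for child in node.children:
            collect(child, Fraction(0))
        tips = sorted(t.label for t in node.tips())  # type: ignore[misc]
        keys[id(node)] = (sum(dists, Fraction(0)) / len(dists), len(tips), tips[0])

    # Kahn-style selection: a node becomes eligible once all of its internal
    # children are ranked; pick the eligible node with the smallest key.
    ranked: list[TreeNode] = []
    done: set[int] = set()
    remaining = list(internal)
    while remaining:
        eligible = [
            n
            for n in remaining
            if all(c.is_tip or id(c) in done for c in n.children)
        ]
        nxt = min(eligible, key=lambda n: keys[id(n)])
        ranked.append(nxt)
        done.add(id(nxt))
        remaining.remove(nxt)
    return ranked


def decompose_into_periods(tree: MutationTree) -> CoalescentPeriodTable:
    """Decompose a tree into coalescent periods with per-period mutation totals.

    Coalescent events (internal nodes) are totally ordered from most recent to
    most ancient; the lineage count starts at ``n`` in the tip period and drops
    by ``children - 1`` at each event (multifurcations drop it by more than
    one, so intermediate period indices may be skipped).  A branch whose ends
    fall in non-adjacent events spans several periods; its mutations are
    apportioned with :func:`apportion_spanning_mutations` using the
    single-period (internode) branches as weights.
    """
    if tree.n_tips < 2:
        raise TreeValidationError("decomposition needs at least 2 tips")

    events = _order_coalescent_events(tree)
    rank = {id(node): r for r, node in enumerate(events, start=1)}
    n = tree.n_tips

    # lineage count during slot s (after the first s events, before event s+1)
    lineage_count = [n]
    for node in events:
        lineage_count.append(lineage_count[-1] - (len(node.children) - 1))
    assert lineage_count[-1] == 1
    n_slots = len(events)  # slots 0 .. n_slots-1, slot s has lineage_count[s]

    def branch_slots(node: TreeNode) -> range:
        child_rank = 0 if node.is_tip else rank[id(node)]
        parent_rank = rank[id(node.parent)]
        return range(child_rank, parent_rank)

    direct_gamma: dict[int, Fraction] = {s: Fraction(0) for s in range(n_slots)}
    spanning: list[tuple[TreeNode, range]] = []
    for node in tree.root.preorder():
        if node is tree.root:
            continue
        slots = branch_slots(node)
        if len(slots) == 1:
            s = slots[0]
            direct_gamma[s] += node.mutations  # type: ignore[operator]
            if (
                node.is_tip
                and node.mutations > TIP_PERIOD_MUTATION_WINDOW  # type: ignore[operator]
            ):
                warnings.warn(
                    f"tip branch {node.label!r} carries {node.mutations} mutations "
                    "within a single coalescent period, outside the plausible "
                    f"0-{TIP_PERIOD_MUTATION_WINDOW} window for one period"
                )
        else:
            spanning.append((node, slots))

    gamma = dict(direct_gamma)
    note = {s: "direct" for s in range(n_slots)}
    for node, slots in spanning:
        label = node.label or "|".join(sorted(t.label for t in node.tips()))  # type: ignore[misc]
        # weights keyed by slot; apportion over lineage-count indices for
        # reporting, but slots are what is contiguous
        assignment = apportion_spanning_mutations(
            node.mutations,  # type: ignore[arg-type]
            list(slots),
            {s: direct_gamma[s] for s in slots},
            branch=label,
        )
        for s, alloc in assignment.allocations:
            if alloc:
                gamma[s] += alloc
                note[s] = "apportioned"

    rows = [
        PeriodRow(index=lineage_count[s], gamma=gamma[s], note=note[s])
        for s in range(n_slots)
    ]
    table = CoalescentPeriodTable(rows)
    assert table.total_mutations() == tree.total_mutations()
    return table


# ---------------------------------------------------------------------------
# period-table TSV I/O
# ---------------------------------------------------------------------------

_PERIOD_HEADER = ("period", "lineages", "mutations")


def read_period_table(path: str | Path | io.TextIOBase) -> CoalescentPeriodTable:
    """Read a coalescent-period table from TSV.

    Expected header columns: ``period``, ``lineages``, ``mutations`` (extra
    columns are ignored).  The ``period`` column must equal the ``lineages``
    column — both conventions name the same quantity, the number of extant
    lineages.  Out-of-order rows are reordered ascending with a log message.
    """
    if isinstance(path, io.TextIOBase):
        text = path.read()
        name = getattr(path, "name", "<stream>")
    else:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"no such period table: {p}")
        text = p.read_text()
        name = str(p)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise TreeValidationError(f"{name}: empty period table")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    missing = [c for c in _PERIOD_HEADER if c not in header]
    if missing:
        raise TreeValidationError(
            f"{name}: missing required column(s) {missing}; expected header "
            f"{list(_PERIOD_HEADER)}"
        )
    idx = {c: header.index(c) for c in _PERIOD_HEADER}
    rows: list[PeriodRow] = []
    for ln_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        try:
            period = int(cells[idx["period"]])
            lineages = int(cells[idx["lineages"]])
            mutations = Fraction(cells[idx["mutations"]].strip())
        except (ValueError, IndexError, ZeroDivisionError) as exc:
            raise TreeValidationError(f"{name}: line {ln_no}: non-numeric cell ({exc})")
        if period != lineages:
            raise TreeValidationError(
                f"{name}: line {ln_no}: period ({period}) != lineages ({lineages}); "
                "both columns index the period by its extant lineage count and "
                "must agree"
            )
        if lineages < 2:
            raise TreeValidationError(f"{name}: line {ln_no}: lineages {lineages} < 2")
        if mutations < 0:
            raise TreeValidationError(f"{name}: line {ln_no}: negative mutations")
        rows.append(PeriodRow(index=lineages, gamma=mutations))
    if [r.index for r in rows] != sorted(r.index for r in rows):
        logger.info("%s: rows out of order; reordered ascending by lineage count", name)
    return CoalescentPeriodTable(rows)


def write_period_table(table: CoalescentPeriodTable, path: str | Path) -> None:
    """Write a period table as TSV (exact: fractional counts round-trip)."""
    lines = ["\t".join(_PERIOD_HEADER)]
    for row in table.rows:
        g = row.gamma
        cell = str(int(g)) if g.denominator == 1 else str(g)
        lines.append(f"{row.index}\t{row.index}\t{cell}")
    Path(path).write_text("\n".join(lines) + "\n")
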