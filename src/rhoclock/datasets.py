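"""Bundled example data: the five-lineage worked example.

``load_five_lineage_tree`` returns a synthetic 5-tip tree constructed so that
its coalescent-period decomposition reproduces the worked example's period
table exactly (gamma = {2: 3, 3: 6, 4: 2, 5: 5}, 16 mutations in total).  The
original figure it emulates is not machine-readable; this stand-in matches the
period structure, not necessarily the branch-level mutation placement, so its
classic rho (7.8) differs from the source genealogy's.

``load_worked_example_periods`` returns the period table itself, the
authoritative input for reproducing the worked example's dating chain.
"""

from __future__ import annotations

from importlib import resources

from .tree import (
    CoalescentPeriodTable,
    MutationTree,
    read_newick_mutation_tree,
    read_period_table,
)

__all__ = [
    "load_five_lineage_tree",
    "load_worked_example_periods",
    "five_lineage_tree_path",
    "worked_example_periods_path",
]


def _data_path(name: str):
    return resources.files("rhoclock") / "data" / name


def five_lineage_tree_path() -> str:
    return str(_data_path("five_lineage_tree.nwk"))


def worked_example_periods_path() -> str:
    return str(_data_path("worked_example_periods.tsv"))


def load_five_lineage_tree() -> MutationTree:
    """The synthetic five-lineage example tree (period table {2:3,3:6,4:2,5:5})."""
    return read_newick_mutation_tree(_data_path("five_lineage_tree.nwk").read_text())


def load_worked_example_periods() -> CoalescentPeriodTable:
    """The worked-example coalescent-period table (four periods, 16 mutations)."""
    return read_period_table(_data_path("worked_example_periods.tsv"))
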