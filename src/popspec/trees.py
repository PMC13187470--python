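"""Shared phylogeny utilities and the population-labelled tree type.

Trees are :class:`skbio.TreeNode` objects throughout the package.  Tips of a
population-labelled tree are genomes; each genome belongs to exactly one
population ("MC"), and a subset of populations may be flagged as specialists.
On disk the labelling is carried in the tip name as ``<genome>|<MC>``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from skbio import TreeNode

__all__ = [
    "PopulationLabeledTree",
    "parse_labeled_newick",
    "patristic_distances",
    "tip_names",
]


def tip_names(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


@dataclass
class PopulationLabeledTree:
    """Rooted tree plus tip -> population map and the specialist flag set.

    Invariants (checked by :meth:`validate`): every tip carries exactly one MC
    label, every MC has >= 3 tips, branch lengths are nonnegative and the
    specialist set is a subset of the MC labels.
    """

    tree: TreeNode
    mc_of_tip: dict[str, str]
    specialist_mcs: set[str] = field(default_factory=set)

    def validate(self, min_tips_per_mc: int = 3) -> None:
        tips = tip_names(self.tree)
        missing = [t for t in tips if t not in self.mc_of_tip]
        if missing:
            raise ValueError(f"tips without MC label: {missing[:5]}")
        counts: dict[str, int] = {}
        for t in tips:
            counts[self.mc_of_tip[t]] = counts.get(self.mc_of_tip[t], 0) + 1
        small = [mc for mc, n in counts.items() if n < min_tips_per_mc]
        if small:
            raise ValueError(
                f"MCs with fewer than {min_tips_per_mc} tips: {sorted(small)}"
            )
        for node in self.tree.traverse():
            if node.length is not None and node.length < 0:
                raise ValueError("negative branch length")
        extra = self.specialist_mcs - set(counts)
        if extra:
            raise ValueError(f"specialist MCs not present in tree: {sorted(extra)}")

    @property
    def mcs(self) -> list[str]:
        return sorted(set(self.mc_of_tip.values()))

    def tips_of_mc(self, mc: str) -> list[str]:
        return [t for t, m in self.mc_of_tip.items() if m == mc]

    def is_specialist_tip(self, tip: str) -> bool:
        return self.mc_of_tip[tip] in self.specialist_mcs

    # -- serialization ------------------------------------------------------

    def to_newick(self) -> str:
        """Newick with tips renamed ``<genome>|<MC>``."""
        tr = self.tree.copy()
        for t in tr.tips():
            t.name = f"{t.name}|{self.mc_of_tip[t.name]}"
        return str(tr).strip()

    @classmethod
    def from_newick(
        cls, newick: str, specialist_mcs: set[str] | None = None
    ) -> "PopulationLabeledTree":
        return parse_labeled_newick(newick, specialist_mcs)


def parse_labeled_newick(
    newick: str, specialist_mcs: set[str] | None = None
) -> PopulationLabeledTree:
    """Parse a newick whose tip names are ``<genome>|<MC>``."""
    tree = TreeNode.read(io.StringIO(newick))
    mc_of_tip: dict[str, str] = {}
    for tip in tree.tips():
        if tip.name is None or "|" not in tip.name:
            raise ValueError(f"tip {tip.name!r} lacks a '|MC' label")
        genome, mc = tip.name.rsplit("|", 1)
        tip.name = genome
        mc_of_tip[genome] = mc
    return PopulationLabeledTree(tree, mc_of_tip, set(specialist_mcs or ()))


def patristic_distances(tree: TreeNode) -> tuple[np.ndarray, list[str]]:
    """Tip-to-tip path-length matrix and the tip order it is indexed by."""
    dm = tree.tip_tip_distances()
    return np.asarray(dm.data, dtype=float), list(dm.ids)
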