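"""Ortholog-group filtering and specialist-exclusive convergent clade detection.

An ortholog group is convergent when some node of its gene tree subtends
leaves from at least two distinct specialist populations and no leaf from any
non-specialist population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from skbio import TreeNode

__all__ = [
    "ConvergenceCall",
    "filter_ogs",
    "detect_specialist_convergent_clade",
    "summarize_convergent_ogs",
]

logger = logging.getLogger(__name__)


@dataclass
class ConvergenceCall:
    og: str
    convergent: bool
    witness_node: str | None
    specialist_mcs_in_clade: frozenset[str]
    clade_size: int


def filter_ogs(pa: pd.DataFrame, min_fraction: float = 0.5) -> list[str]:
    """Keep ortholog groups present in at least `min_fraction` of genomes."""
    if pa.empty:
        raise ValueError("empty presence/absence matrix")
    prevalence = (pa > 0).sum(axis=0) / pa.shape[0]
    return [og for og in pa.columns if prevalence[og] >= min_fraction]


def detect_specialist_convergent_clade(
    gene_tree: TreeNode,
    mc_of_leaf: dict[str, str],
    specialist_mcs: set[str],
    og: str = "OG",
) -> ConvergenceCall:
    """Scan internal nodes for a specialist-exclusive multi-MC clade.

    A qualifying node's descendant leaves come from >= 2 distinct specialist
    MCs and from no non-specialist MC; among qualifying nodes the largest
    clade is reported as the witness.  Unrooted input is midpoint-rooted.
    """
    tree = gene_tree
    if len(tree.children) > 2:
        logger.warning("unrooted gene tree for %s: midpoint rooting", og)
        tree = tree.root_at_midpoint()
    leaves = [t.name for t in tree.tips()]
    unknown = [l for l in leaves if l not in mc_of_leaf]
    if unknown:
        raise ValueError(f"leaves without MC label: {unknown[:5]}")

    best: tuple[int, str | None, frozenset[str]] = (0, None, frozenset())
    for idx, node in enumerate(tree.non_tips(include_self=True)):
        mcs = {mc_of_leaf[t.name] for t in node.tips()}
        size = sum(1 for _ in node.tips())
        spec_here = mcs & specialist_mcs
        if len(spec_here) >= 2 and not (mcs - specialist_mcs):
            if size > best[0]:
                name = node.name or f"node{idx}"
                best = (size, name, frozenset(spec_here))
    convergent = best[0] > 0
    return ConvergenceCall(
        og=og,
        convergent=convergent,
        witness_node=best[1],
        specialist_mcs_in_clade=best[2],
        clade_size=best[0],
    )


def summarize_convergent_ogs(
    calls: list[ConvergenceCall], annotations: dict[str, str] | None = None
) -> pd.DataFrame:
    """Table of convergent OGs with witness clade composition and annotation."""
    annotations = annotations or {}
    rows = []
    for c in calls:
        if not c.convergent:
            continue
        rows.append({
            "og": c.og,
            "witness_node": c.witness_node,
            "specialist_mcs_in_clade": ",".join(sorted(c.specialist_mcs_in_clade)),
            "clade_size": c.clade_size,
            "annotation": annotations.get(c.og, ""),
        })
    return pd.DataFrame(
        rows,
        columns=["og", "witness_node", "specialist_mcs_in_clade", "clade_size", "annotation"],
    )
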