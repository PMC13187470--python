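"""Assign ASVs to populations by joint-tree placement.

Queries are aligned into the reference coordinate frame, a joint
neighbor-joining tree is built over reference and query sequences, and each
query is assigned to the population contributing strictly more than a
threshold fraction (default 0.80) of the reference tips descending from its
parental node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "JointAlignment",
    "JointTree",
    "AssignmentResult",
    "align_queries_to_reference",
    "build_joint_tree",
    "assign_asv_to_population",
    "assign_all",
    "aggregate_population_abundance",
]

logger = logging.getLogger(__name__)

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "-": -1}


@dataclass
class JointAlignment:
    """Reference rows (unchanged) plus queries mapped into reference columns."""

    ids: list[str]
    rows: list[str]
    kind: dict[str, str]  # id -> "reference" | "query"
    excluded_queries: list[str] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class JointTree:
    tree: TreeNode
    tip_kind: dict[str, str]
    mc_of_reference: dict[str, str]

    def validate(self) -> None:
        refs = [t for t, k in self.tip_kind.items() if k == "reference"]
        if not refs:
            raise ValueError("joint tree needs >= 1 reference tip")
        missing = [r for r in refs if r not in self.mc_of_reference]
        if missing:
            raise ValueError(f"reference tips without MC label: {missing[:5]}")


@dataclass
class AssignmentResult:
    asv_id: str
    assigned_mc: str | None
    supporting_fraction: float
    n_reference_tips_considered: int
    ancestor_depth_used: int


def _consensus(rows: list[str]) -> str:
    arr = np.array([[_ENC.get(c, -1) for c in r] for r in rows])
    cons = []
    for j in range(arr.shape[1]):
        col = arr[:, j]
        col = col[col >= 0]
        if col.size == 0:
            cons.append("-")
        else:
            cons.append("ACGT"[np.bincount(col, minlength=4).argmax()])
    return "".join(cons)


def align_queries_to_reference(
    reference_ids: list[str],
    reference_rows: list[str],
    asv_sequences: dict[str, str],
    *,
    min_identity: float = 0.5,
) -> JointAlignment:
    """Profile-align queries against the reference alignment.

    Each query is globally aligned (affine gaps) to the ungapped reference
    consensus, then projected onto reference columns; query bases falling in
    insertions relative to the consensus are discarded so the reference
    coordinate frame is preserved.  Queries under `min_identity` to the
    consensus are excluded and logged.
    """
    if not reference_rows:
        raise ValueError("reference alignment is empty")
    cons = _consensus(reference_rows)
    core_cols = [j for j, c in enumerate(cons) if c != "-"]
    core = "".join(cons[j] for j in core_cols)
    L = len(reference_rows[0])

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-4,
        extend_gap_score=-1,
        open_end_gap_score=-1,
        extend_end_gap_score=-0.5,
    )

    ids = list(reference_ids)
    rows = list(reference_rows)
    kind = {i: "reference" for i in reference_ids}
    excluded: list[str] = []
    for qid in sorted(asv_sequences):
        qseq = asv_sequences[qid]
        aln = aligner.align(core, qseq)[0]
        row = ["-"] * L
        matched = 0
        total = 0
        for (ts, te), (qs, qe) in zip(*aln.aligned):
            for k in range(te - ts):
                col = core_cols[ts + k]
                row[col] = qseq[qs + k]
                total += 1
                if qseq[qs + k] == core[ts + k]:
                    matched += 1
        identity = matched / max(total, 1)
        if identity < min_identity or total == 0:
            logger.warning("query %s excluded: identity %.2f < %.2f", qid, identity, min_identity)
            excluded.append(qid)
            continue
        ids.append(qid)
        rows.append("".join(row))
        kind[qid] = "query"
    return JointAlignment(ids=ids, rows=rows, kind=kind, excluded_queries=excluded)


def _jc_distance_matrix(ids: list[str], rows: list[str]) -> DistanceMatrix:
    arr = np.array([[_ENC.get(c, -1) for c in r] for r in rows])
    n = len(ids)
    d = np.zeros((n, n))
    valid = arr >= 0
    for i in range(n):
        both = valid[i] & valid
        diff = (arr[i] != arr) & both
        nv = both.sum(axis=1)
        p = np.where(nv > 0, diff.sum(axis=1) / np.maximum(nv, 1), 0.0)
        p = np.minimum(p, 0.74)  # JC correction undefined at p >= 0.75
        d[i] = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids)


def build_joint_tree(
    joint: JointAlignment, mc_of_reference: dict[str, str]
) -> JointTree:
    """Neighbor-joining on Jukes-Cantor distances, midpoint-rooted.

    Rows are sorted lexicographically by name before distance computation so
    the result is independent of input order.
    """
    if len(joint.ids) < 4:
        raise ValueError("need >= 4 sequences for a joint tree")
    if len(set(joint.ids)) != len(joint.ids):
        raise ValueError("duplicate tip names in joint alignment")
    order = sorted(range(len(joint.ids)), key=lambda i: joint.ids[i])
    ids = [joint.ids[i] for i in order]
    rows = [joint.rows[i] for i in order]
    dm = _jc_distance_matrix(ids, rows)
    tree = nj(dm)
    tree = tree.root_at_midpoint()
    jt = JointTree(tree=tree, tip_kind=dict(joint.kind), mc_of_reference=dict(mc_of_reference))
    jt.validate()
    return jt


def assign_asv_to_population(
    jt: JointTree, asv_id: str, tau: float = 0.80
) -> AssignmentResult:
    """Parental-node majority rule: assign the plurality MC among reference
    tips under the ASV's parent iff its fraction is strictly greater than tau.

    If the parent subtends no reference tip, ascend to the nearest ancestor
    that does and apply the rule once there.
    """
    if jt.tip_kind.get(asv_id) == "reference":
        raise ValueError(f"{asv_id} is a reference tip, not a query")
    if jt.tip_kind.get(asv_id) != "query":
        raise ValueError(f"{asv_id} not found among query tips")
    tip = next((t for t in jt.tree.tips() if t.name == asv_id), None)
    if tip is None:
        raise ValueError(f"tip {asv_id} absent from tree")

    node = tip.parent
    depth = 0
    while node is not None:
        ref_tips = [
            t.name for t in node.tips() if jt.tip_kind.get(t.name) == "reference"
        ]
        if ref_tips:
            break
        node = node.parent
        depth += 1
    if node is None:
        return AssignmentResult(asv_id, None, 0.0, 0, depth)

    counts: dict[str, int] = {}
    for r in ref_tips:
        mc = jt.mc_of_reference[r]
        counts[mc] = counts.get(mc, 0) + 1
    best = max(counts.values())
    winners = [mc for mc, c in counts.items() if c == best]
    fraction = best / len(ref_tips)
    assigned = winners[0] if (len(winners) == 1 and fraction > tau) else None
    return AssignmentResult(
        asv_id=asv_id,
        assigned_mc=assigned,
        supporting_fraction=fraction,
        n_reference_tips_considered=len(ref_tips),
        ancestor_depth_used=depth,
    )


def assign_all(jt: JointTree, tau: float = 0.80) -> list[AssignmentResult]:
    queries = sorted(t for t, k in jt.tip_kind.items() if k == "query")
    return [assign_asv_to_population(jt, q, tau) for q in queries]


def aggregate_population_abundance(
    counts: pd.DataFrame, assignments: list[AssignmentResult]
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Sum assigned-ASV counts per MC and normalise per sample.

    Returns (MC x sample relative abundances over assigned reads, per-sample
    unassigned read fraction, samples flagged for having zero assigned reads).
    """
    by_asv = {a.asv_id: a.assigned_mc for a in assignments}
    missing = [a for a in counts.index if a not in by_asv]
    if missing:
        raise ValueError(f"ASVs without assignment record: {missing[:5]}")
    mcs = sorted({mc for mc in by_asv.values() if mc is not None})
    mc_counts = pd.DataFrame(0.0, index=mcs, columns=counts.columns)
    unassigned = pd.Series(0.0, index=counts.columns)
    for asv in counts.index:
        mc = by_asv[asv]
        if mc is None:
            unassigned += counts.loc[asv]
        else:
            mc_counts.loc[mc] += counts.loc[asv]
    totals = mc_counts.sum(axis=0)
    flagged = [s for s in counts.columns if totals[s] == 0]
    rel = mc_counts.divide(totals.where(totals > 0), axis=1)
    unassigned_frac = unassigned / counts.sum(axis=0).replace(0, np.nan)
    return rel, unassigned_frac, flagged
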