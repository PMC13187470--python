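"""Plain-text I/O shared across stages (FASTA, TSV, newick).

All user-facing coordinates are 1-based inclusive; count tables are written
with samples as columns.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_counts(path: str | Path) -> pd.DataFrame:
    """ASV/MC x sample integer count table."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_group_map(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """TSV with columns id, group (ingroup/outgroup) and optional mc."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    group = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    mc = {}
    if df.shape[1] > 2:
        mc = {
            i: m
            for i, m in zip(df.iloc[:, 0], df.iloc[:, 2])
            if isinstance(m, str) and m
        }
    return group, mc


def read_mc_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV: leaf/genome id -> MC label."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    if df.iloc[0, 0] in ("id", "genome", "leaf"):  # tolerate a header row
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path))


def write_newick(path: str | Path, tree: TreeNode) -> None:
    Path(path).write_text(str(tree).strip() + "\n")


def tree_to_newick_str(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
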