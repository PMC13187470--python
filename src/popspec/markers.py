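"""Degenerate primer design resolving populations within a genus.

Primer pairs are enumerated from a labelled alignment under three criteria:
each primer covers at least one ingroup/outgroup discriminating SNP, primer
length is 17-25 bp with product size strictly below 600 bp, and the pair shows
no 3'-anchored cross-complementarity.  Primer sequences are minimal-IUPAC
degenerate consensus strings over the ingroup rows of their window.

Coordinates are 1-based inclusive alignment columns; product sizes are
measured on the ungapped ingroup consensus so that the arithmetic
``reverse_end - forward_start + 1`` reproduces printed amplicon lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product as iter_product

import numpy as np
from skbio import TreeNode

__all__ = [
    "LabeledAlignment",
    "PrimerPair",
    "ResolutionScore",
    "IUPAC",
    "IUPAC_SETS",
    "find_discriminating_snps",
    "degenerate_consensus",
    "expand_iupac",
    "enumerate_primer_pairs",
    "check_cross_complementarity",
    "product_size",
    "score_population_resolution",
    "wallace_tm",
]

# frozenset(base set) -> IUPAC code
IUPAC: dict[frozenset[str], str] = {
    frozenset("A"): "A",
    frozenset("C"): "C",
    frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
    frozenset("CGT"): "B",
    frozenset("AGT"): "D",
    frozenset("ACT"): "H",
    frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}
IUPAC_SETS: dict[str, frozenset[str]] = {v: k for k, v in IUPAC.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def expand_iupac(code: str) -> frozenset[str]:
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def _revcomp_sets(seq: str) -> list[frozenset[str]]:
    return [
        frozenset(_COMPLEMENT[b] for b in expand_iupac(c)) for c in reversed(seq)
    ]


@dataclass
class LabeledAlignment:
    """Aligned rows labelled by genome, ingroup/outgroup membership and MC."""

    ids: list[str]
    rows: list[str]
    group_of_row: dict[str, str]  # id -> "ingroup" | "outgroup"
    mc_of_row: dict[str, str] = field(default_factory=dict)
    degenerate: bool = False

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ingroup_rows(self) -> list[str]:
        return [r for i, r in zip(self.ids, self.rows) if self.group_of_row[i] == "ingroup"]

    def outgroup_rows(self) -> list[str]:
        return [r for i, r in zip(self.ids, self.rows) if self.group_of_row[i] == "outgroup"]

    def column(self, pos: int, rows: list[str]) -> list[str]:
        """Residues of 1-based column `pos` over the given rows."""
        return [r[pos - 1] for r in rows]


@dataclass
class PrimerPair:
    forward_seq: str
    reverse_seq: str
    forward_start: int  # 1-based alignment column of forward 5' end
    reverse_end: int  # 1-based alignment column of amplicon 3' end
    product_size: int
    snp_positions_covered: tuple[tuple[int, ...], tuple[int, ...]]
    degeneracy: int
    tm_advisory: tuple[float, float] = (0.0, 0.0)

    def validate(self, max_product: int = 600, min_len: int = 17, max_len: int = 25) -> None:
        for seq in (self.forward_seq, self.reverse_seq):
            if not min_len <= len(seq) <= max_len:
                raise ValueError(f"primer length {len(seq)} outside [{min_len},{max_len}]")
        if self.product_size >= max_product:
            raise ValueError(f"product size {self.product_size} not < {max_product}")
        if not all(len(s) >= 1 for s in self.snp_positions_covered):
            raise ValueError("each primer must cover >= 1 SNP")


@dataclass
class ResolutionScore:
    fraction_monophyletic: float
    monophyly: dict[str, bool]


def find_discriminating_snps(aln: LabeledAlignment) -> list[int]:
    """1-based columns where ingroup and outgroup residue sets are disjoint.

    Residues are expanded through IUPAC codes before the disjointness test;
    any column containing a gap in any row is excluded.
    """
    ingroup = aln.ingroup_rows()
    outgroup = aln.outgroup_rows()
    if not ingroup or not outgroup:
        raise ValueError("both ingroup and outgroup rows are required")
    positions = []
    for pos in range(1, aln.length + 1):
        col_in = aln.column(pos, ingroup)
        col_out = aln.column(pos, outgroup)
        if any(c == "-" for c in col_in + col_out):
            continue
        set_in: set[str] = set()
        for c in col_in:
            set_in |= expand_iupac(c)
        set_out: set[str] = set()
        for c in col_out:
            set_out |= expand_iupac(c)
        if not set_in & set_out:
            positions.append(pos)
    return positions


def degenerate_consensus(residues) -> str:
    """Minimal IUPAC code covering exactly the observed base set."""
    bases = frozenset(b.upper() for b in residues)
    if not bases:
        raise ValueError("empty residue set")
    if not bases <= set("ACGT"):
        raise ValueError(f"residues outside ACGT: {sorted(bases - set('ACGT'))}")
    return IUPAC[bases]


def check_cross_complementarity(forward: str, reverse: str, k: int = 4) -> bool:
    """True if the primers are cross-complementary (pair must be rejected).

    The 3'-terminal k-mer of either primer is reverse-complemented and scanned
    against every window of the other primer; a hit requires the expanded base
    sets to intersect at every position.
    """
    if not forward or not reverse:
        raise ValueError("primers must be non-empty")
    if k > len(forward) or k > len(reverse):
        raise ValueError(f"k={k} exceeds a primer length")

    def hits(three_prime_of: str, other: str) -> bool:
        kmer_rc = _revcomp_sets(three_prime_of[-k:])
        other_sets = [expand_iupac(c) for c in other]
        for start in range(len(other) - k + 1):
            if all(kmer_rc[i] & other_sets[start + i] for i in range(k)):
                return True
        return False

    return hits(forward, reverse) or hits(reverse, forward)


def product_size(forward_name_pos: int, reverse_name_pos: int) -> int:
    """Amplicon length from primer position names (5' start / 3' end)."""
    if reverse_name_pos < forward_name_pos:
        raise ValueError("reverse position precedes forward position")
    return reverse_name_pos - forward_name_pos + 1


def wallace_tm(seq: str) -> float:
    """Advisory 2+4 rule melting temperature, averaging degenerate bases."""
    tm = 0.0
    for c in seq:
        bases = expand_iupac(c)
        gc = sum(1 for b in bases if b in "GC") / len(bases)
        tm += 2.0 + 2.0 * gc
    return tm


def _ungapped_positions(consensus_row: list[str]) -> dict[int, int]:
    """Map 1-based alignment column -> 1-based ungapped-consensus position."""
    mapping = {}
    pos = 0
    for col, c in enumerate(consensus_row, start=1):
        if c != "-":
            pos += 1
            mapping[col] = pos
    return mapping


def enumerate_primer_pairs(
    aln: LabeledAlignment,
    snp_positions: list[int] | None = None,
    *,
    min_len: int = 17,
    max_len: int = 25,
    max_product: int = 600,
    max_degeneracy: int = 16,
    comp_k: int = 4,
    max_pairs: int | None = None,
) -> list[PrimerPair]:
    """Exhaustive enumeration of primer pairs satisfying all three criteria.

    Windows never include a column with a gap in any ingroup row.  Pairs are
    sorted by ascending degeneracy then descending total SNP coverage.
    """
    if snp_positions is None:
        snp_positions = find_discriminating_snps(aln)
    if not snp_positions:
        raise ValueError("no discriminating SNP positions supplied")
    snp_set = set(snp_positions)
    ingroup = aln.ingroup_rows()
    if not ingroup:
        raise ValueError("alignment has no ingroup rows")
    length = aln.length

    gap_col = [any(r[i] == "-" for r in ingroup) for i in range(length)]
    consensus = []
    for i in range(length):
        if gap_col[i]:
            consensus.append("-")
        else:
            consensus.append(degenerate_consensus([r[i] for r in ingroup]))
    degen = [len(expand_iupac(c)) if c != "-" else 0 for c in consensus]
    coord = _ungapped_positions(consensus)

    # candidate windows: gap-free, length in range, degeneracy capped, >=1 SNP
    windows: list[tuple[int, int, int]] = []  # (start_col, end_col, degeneracy)
    for start in range(1, length + 1):
        d = 1
        for end in range(start, min(start + max_len, length + 1)):
            if gap_col[end - 1]:
                break
            d *= degen[end - 1]
            if d > max_degeneracy:
                break
            wlen = end - start + 1
            if wlen >= min_len and any(p in snp_set for p in range(start, end + 1)):
                windows.append((start, end, d))

    def window_seq(start: int, end: int) -> str:
        return "".join(consensus[start - 1 : end])

    def window_snps(start: int, end: int) -> tuple[int, ...]:
        return tuple(p for p in range(start, end + 1) if p in snp_set)

    def revcomp_iupac(seq: str) -> str:
        return "".join(
            IUPAC[frozenset(_COMPLEMENT[b] for b in expand_iupac(c))]
            for c in reversed(seq)
        )

    pairs: list[PrimerPair] = []
    for (fs, fe, fd), (rs, re_, rd) in iter_product(windows, windows):
        if rs <= fe:  # windows must not overlap and reverse must be downstream
            continue
        size = coord[re_] - coord[fs] + 1
        if size >= max_product:
            continue
        fwd = window_seq(fs, fe)
        rev = revcomp_iupac(window_seq(rs, re_))
        if check_cross_complementarity(fwd, rev, k=comp_k):
            continue
        pairs.append(
            PrimerPair(
                forward_seq=fwd,
                reverse_seq=rev,
                forward_start=fs,
                reverse_end=re_,
                product_size=size,
                snp_positions_covered=(window_snps(fs, fe), window_snps(rs, re_)),
                degeneracy=fd * rd,
                tm_advisory=(wallace_tm(fwd), wallace_tm(rev)),
            )
        )
    pairs.sort(
        key=lambda p: (
            p.degeneracy,
            -(len(p.snp_positions_covered[0]) + len(p.snp_positions_covered[1])),
            p.forward_start,
            p.reverse_end,
        )
    )
    if max_pairs is not None:
        pairs = pairs[:max_pairs]
    return pairs


def score_population_resolution(tree: TreeNode, mc_of_tip: dict[str, str]) -> ResolutionScore:
    """Fraction of MCs forming monophyletic clades on a rooted tree."""
    tips = [t.name for t in tree.tips()]
    unlabeled = [t for t in tips if t not in mc_of_tip]
    if unlabeled:
        raise ValueError(f"unlabelled tips: {unlabeled[:5]}")
    mcs = sorted(set(mc_of_tip[t] for t in tips))
    monophyly: dict[str, bool] = {}
    for mc in mcs:
        members = set(t for t in tips if mc_of_tip[t] == mc)
        if len(members) == 1:
            monophyly[mc] = True
            continue
        lca = tree.lca(list(members))
        clade = set(t.name for t in lca.tips())
        monophyly[mc] = clade == members
    frac = sum(monophyly.values()) / len(mcs)
    return ResolutionScore(fraction_monophyletic=frac, monophyly=monophyly)
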