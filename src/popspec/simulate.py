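"""Ground-truth-known synthetic inputs for every downstream stage.

The generator plants a known structure: a pure-birth backbone of populations
(MCs) with shallow within-population subtrees, marker sequences evolved under
Jukes-Cantor, Dirichlet-multinomial ASV counts with a specialist enrichment
at western sites, gene presence/absence from a two-state Markov chain with a
specialist-conditional rate bias on planted genes, and Brownian phenotypes
with an additive specialist shift.  One master seed determines everything;
each stage draws from its own deterministic child stream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import child_rng
from .markers import LabeledAlignment
from .trees import PopulationLabeledTree

__all__ = [
    "SimulationConfig",
    "AsvTable",
    "GenePAMatrix",
    "simulate_population_tree",
    "make_metadata",
    "simulate_marker_alignments",
    "simulate_asv_tables",
    "simulate_gene_pa",
    "simulate_rates",
    "MARKERS",
]

MARKERS = ("taxonomic_1", "taxonomic_2", "functional")
_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """All knobs of the synthetic scenario; `seed` fully determines outputs."""

    n_populations: int = 20
    isolates_per_population: int = 4
    n_specialists: int = 4
    n_sites: int = 4
    n_western_sites: int = 2
    samples_per_site: int = 6
    enrichment_log_fold: float = np.log(10.0)
    dm_overdispersion: float = 50.0  # Dirichlet concentration total
    bm_rate: float = 1.0  # Brownian sigma^2
    specialist_rate_shift: float = 0.0
    gene_gain_rate: float = 0.5
    gene_loss_rate: float = 0.5
    functional_marker_carriage: float = 0.6
    seed: int = 0
    # secondary knobs
    within_depth_fraction: float = 0.02
    subst_scale: float = 0.25  # expected subs/site over the full tree depth
    marker_length: int = 300
    sequencing_depth: int = 2000
    read_noise: float = 0.0
    n_genes: int = 50
    n_planted_genes: int = 5
    planted_gene_bias: float = 8.0
    n_outgroups: int = 3
    outgroup_extra_depth: float = 0.8
    n_diagnostic_columns: int = 10

    def validate(self) -> None:
        if self.n_populations < 2:
            raise ValueError("n_populations must be >= 2")
        if self.isolates_per_population < 3:
            raise ValueError("isolates_per_population must be >= 3")
        if not 0 <= self.n_specialists <= self.n_populations:
            raise ValueError("n_specialists out of range")
        if self.n_sites < 2 or not 1 <= self.n_western_sites < self.n_sites:
            raise ValueError("need >= 1 western and >= 1 non-western site")
        if self.samples_per_site < 1:
            raise ValueError("samples_per_site must be >= 1")
        if self.dm_overdispersion <= 0:
            raise ValueError("dm_overdispersion must be > 0")
        if self.bm_rate <= 0:
            raise ValueError("bm_rate must be > 0")
        if self.gene_gain_rate <= 0 or self.gene_loss_rate <= 0:
            raise ValueError("gene gain/loss rates must be > 0")
        if not 0 <= self.functional_marker_carriage <= 1:
            raise ValueError("functional_marker_carriage must be in [0,1]")
        if self.sequencing_depth <= 0:
            raise ValueError("sequencing_depth must be > 0")
        if not 0 <= self.read_noise < 1:
            raise ValueError("read_noise must be in [0,1)")
        if not 0 < self.within_depth_fraction < 0.05:
            raise ValueError("within_depth_fraction must be in (0, 0.05)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)


@dataclass
class AsvTable:
    """ASV x sample integer counts with sequences and generation ground truth."""

    counts: pd.DataFrame  # index = asv ids, columns = sample ids
    sequences: dict[str, str]
    marker: str
    true_mc_of_asv: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any() or not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be nonnegative integers")
        if (vals.sum(axis=1) == 0).any():
            raise ValueError("every ASV row must have a nonzero entry")
        for s in self.sequences.values():
            if set(s) - set("ACGT"):
                raise ValueError("ASV sequences must be over ACGT")


@dataclass
class GenePAMatrix:
    """Genomes x genes binary presence/absence with planted-gene ground truth."""

    table: pd.DataFrame  # index = genome ids, columns = gene ids, values 0/1
    planted_genes: set[str] = field(default_factory=set)
    invariant_genes: set[str] = field(default_factory=set)


# ---------------------------------------------------------------------------
# tree simulation


def _yule_ultrametric(rng: np.random.Generator, n: int, names: list[str]) -> TreeNode:
    """Pure-birth tree over `names`, rescaled to depth 1 (ultrametric)."""
    if n == 1:
        return TreeNode(name=names[0], length=1.0)
    root = TreeNode()
    split_age: dict[int, float] = {id(root): 0.0}
    active = [root]
    t = 0.0
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        if k > 1:  # root splits at age 0; later splits at accumulated age
            idx = int(rng.integers(len(active)))
            node = active.pop(idx)
            split_age[id(node)] = t
        else:
            node = active.pop()
            split_age[id(node)] = 0.0
        left, right = TreeNode(), TreeNode()
        node.extend([left, right])
        active.extend([left, right])
    total = t + rng.exponential(1.0 / n)
    for name, tip in zip(names, active):
        tip.name = name
    for node in root.traverse(include_self=True):
        if node.parent is None:
            node.length = None
            continue
        node_age = total if node.is_tip() else split_age[id(node)]
        node.length = (node_age - split_age[id(node.parent)]) / total
    return root


def simulate_population_tree(config: SimulationConfig) -> PopulationLabeledTree:
    """Pure-birth MC backbone with shallow within-MC subtrees, total depth 1."""
    config.validate()
    rng = child_rng(config.seed, "population_tree")
    n_mc = config.n_populations
    mc_names = [f"MC{i + 1}" for i in range(n_mc)]
    backbone = _yule_ultrametric(rng, n_mc, mc_names)

    frac = config.within_depth_fraction
    mc_of_tip: dict[str, str] = {}
    for tip in list(backbone.tips()):
        mc = tip.name
        k = config.isolates_per_population
        genome_names = [f"{mc}g{j + 1}" for j in range(k)]
        sub = _yule_ultrametric(rng, k, genome_names)
        # scale subtree to the configured fraction of total depth and splice
        for node in sub.traverse(include_self=True):
            node.length = (node.length or 0.0) * frac
        # clamp short backbone terminal branches so between-MC patristic
        # distances always exceed within-MC ones (2*5*frac > 2*frac)
        sub.length = max(tip.length - frac, 5.0 * frac)
        parent = tip.parent
        parent.remove(tip)
        parent.append(sub)
        for g in genome_names:
            mc_of_tip[g] = mc

    specialists: set[str] = set()
    if config.n_specialists:
        chosen = rng.choice(n_mc, size=config.n_specialists, replace=False)
        specialists = {mc_names[i] for i in sorted(chosen)}

    result = PopulationLabeledTree(backbone, mc_of_tip, specialists)
    result.validate()
    return result


# ---------------------------------------------------------------------------
# metadata


def make_metadata(config: SimulationConfig) -> pd.DataFrame:
    """Per-sample site, site_group, host, compartment and nutrient covariates.

    Western sites carry elevated nitrogen and phosphorus, giving the nutrient
    gradient that specialist enrichment is planted along.
    """
    config.validate()
    rng = child_rng(config.seed, "metadata")
    rows = []
    hosts = ["hostA", "hostB", "hostC"]
    compartments = ["mucus", "tissue", "skeleton"]
    # site-level nutrient means (uM); western elevated
    base = {"nitrate": 1.0, "nitrite": 0.1, "ammonia": 0.5, "total_phosphorus": 0.1}
    western_mult = {"nitrate": 8.0, "nitrite": 4.0, "ammonia": 3.0, "total_phosphorus": 5.0}
    k = 0
    for s in range(config.n_sites):
        western = s < config.n_western_sites
        site = f"{'W' if western else 'E'}{s + 1}"
        means = {
            v: base[v] * (western_mult[v] if western else 1.0) for v in base
        }
        for _ in range(config.samples_per_site):
            row = {
                "sample_id": f"S{k + 1:03d}",
                "site": site,
                "site_group": "western" if western else "non-western",
                "host": hosts[k % len(hosts)],
                "compartment": compartments[k % len(compartments)],
            }
            for v, m in means.items():
                row[v] = float(m * rng.lognormal(mean=0.0, sigma=0.25))
            rows.append(row)
            k += 1
    return pd.DataFrame(rows).set_index("sample_id")


def site_group_of_site(site: str) -> str:
    """site_group is a pure function of the site label."""
    return "western" if site.startswith("W") else "non-western"


# ---------------------------------------------------------------------------
# sequence evolution


def _jc_evolve(rng: np.random.Generator, seq: np.ndarray, dist: float,
               frozen: np.ndarray | None = None) -> np.ndarray:
    """One Jukes-Cantor step over branch length `dist` (subs/site)."""
    p = 0.75 * (1.0 - np.exp(-4.0 * dist / 3.0))
    hit = rng.random(seq.size) < p
    if frozen is not None:
        hit &= ~frozen
    out = seq.copy()
    if hit.any():
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    return out


def _evolve_along_tree(
    rng: np.random.Generator,
    tree: TreeNode,
    root_seq: np.ndarray,
    frozen: np.ndarray | None = None,
    scale: float = 1.0,
) -> dict[str, np.ndarray]:
    seqs: dict[str, np.ndarray] = {}
    stack = [(tree, root_seq)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            child_seq = _jc_evolve(rng, seq, scale * (child.length or 0.0), frozen)
            if child.is_tip():
                seqs[child.name] = child_seq
            else:
                stack.append((child, child_seq))
    return seqs


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


def simulate_marker_alignments(
    tree: PopulationLabeledTree, config: SimulationConfig
) -> dict[str, LabeledAlignment]:
    """Evolve one alignment per marker (plus outgroup rows) under Jukes-Cantor.

    Taxonomic markers cover every tip; the functional marker covers a tip with
    probability `functional_marker_carriage` (specialist tips always carry
    it).  Outgroups descend from a deeper ancestor and carry fixed diagnostic
    states at evenly spaced columns where the ingroup is frozen, guaranteeing
    discriminating SNP sites for primer design.
    """
    tips = [t.name for t in tree.tree.tips()]
    if not tips:
        raise ValueError("empty tree")
    L = config.marker_length
    diag = np.linspace(0, L - 1, config.n_diagnostic_columns, dtype=int)
    frozen = np.zeros(L, dtype=bool)
    frozen[diag] = True

    out: dict[str, LabeledAlignment] = {}
    for marker in MARKERS:
        rng = child_rng(config.seed, f"marker:{marker}")
        root_seq = rng.integers(0, 4, size=L)
        tip_seqs = _evolve_along_tree(
            rng, tree.tree, root_seq, frozen, scale=config.subst_scale
        )

        if marker == "functional":
            carriers = [
                t
                for t in tips
                if tree.is_specialist_tip(t)
                or rng.random() < config.functional_marker_carriage
            ]
        else:
            carriers = list(tips)

        ids, rows = [], []
        group: dict[str, str] = {}
        mc_of_row: dict[str, str] = {}
        for t in sorted(carriers):
            ids.append(t)
            rows.append(_to_str(tip_seqs[t]))
            group[t] = "ingroup"
            mc_of_row[t] = tree.mc_of_tip[t]

        # outgroups: deeper ancestor, diagnostic columns forced to a different base
        og_root = _jc_evolve(rng, root_seq, config.outgroup_extra_depth, frozen)
        og_root[diag] = (root_seq[diag] + 1) % 4
        for j in range(config.n_outgroups):
            og_seq = _jc_evolve(rng, og_root, 0.3, frozen)
            name = f"OUT{j + 1}"
            ids.append(name)
            rows.append(_to_str(og_seq))
            group[name] = "outgroup"

        degenerate = len(carriers) == 0
        out[marker] = LabeledAlignment(
            ids=ids, rows=rows, group_of_row=group, mc_of_row=mc_of_row,
            degenerate=degenerate,
        )
    return out


# ---------------------------------------------------------------------------
# ASV count tables


def simulate_asv_tables(
    tree: PopulationLabeledTree,
    metadata: pd.DataFrame,
    config: SimulationConfig,
    alignments: dict[str, LabeledAlignment] | None = None,
) -> dict[str, AsvTable]:
    """Dirichlet-multinomial counts per marker with planted western enrichment.

    Per sample, MC relative abundances are Dirichlet with concentration
    theta * pi(site) where log pi is an MC baseline plus `enrichment_log_fold`
    for specialist MCs at western sites; reads are multinomial at the
    configured depth and attributed to tip marker sequences.
    """
    config.validate()
    if metadata["site_group"].nunique() < 2:
        raise ValueError("metadata must define >= 2 site_groups")
    if alignments is None:
        alignments = simulate_marker_alignments(tree, config)
    rng = child_rng(config.seed, "asv_tables")
    mcs = tree.mcs
    n_mc = len(mcs)
    is_spec = np.array([mc in tree.specialist_mcs for mc in mcs])
    base_log = rng.normal(0.0, 0.5, size=n_mc)  # per-MC baseline, fixed per run

    tables: dict[str, AsvTable] = {}
    for marker in MARKERS:
        aln = alignments[marker]
        carriers = [i for i in aln.ids if aln.group_of_row[i] == "ingroup"]
        seq_of_tip = {
            i: r for i, r in zip(aln.ids, aln.rows) if aln.group_of_row[i] == "ingroup"
        }
        tips_by_mc = {mc: [t for t in carriers if tree.mc_of_tip[t] == mc] for mc in mcs}
        carrier_mc = np.array([len(tips_by_mc[mc]) > 0 for mc in mcs])
        if not carrier_mc.any():
            tables[marker] = AsvTable(
                counts=pd.DataFrame(index=[], columns=list(metadata.index)),
                sequences={}, marker=marker,
            )
            continue

        counts_per_tip: dict[str, dict[str, int]] = {t: {} for t in carriers}
        for sample_id, row in metadata.iterrows():
            western = row["site_group"] == "western"
            log_pi = base_log.copy()
            if western:
                log_pi = log_pi + config.enrichment_log_fold * is_spec
            pi = np.exp(log_pi)
            pi[~carrier_mc] = 0.0
            pi /= pi.sum()
            alpha = config.dm_overdispersion * pi
            p_mc = np.zeros(n_mc)
            nz = alpha > 0
            p_mc[nz] = rng.dirichlet(alpha[nz])
            mc_counts = rng.multinomial(config.sequencing_depth, p_mc)
            for mc, c in zip(mcs, mc_counts):
                if c == 0:
                    continue
                members = tips_by_mc[mc]
                split = rng.multinomial(c, np.full(len(members), 1.0 / len(members)))
                for t, ct in zip(members, split):
                    if ct:
                        counts_per_tip[t][sample_id] = (
                            counts_per_tip[t].get(sample_id, 0) + int(ct)
                        )

        # collapse tip sequences into ASVs (identical sequences merge)
        seq_counts: dict[str, dict[str, int]] = {}
        seq_mcs: dict[str, set[str]] = {}
        for t in carriers:
            seq = seq_of_tip[t]
            if config.read_noise > 0:
                seq = _noisy_variant(rng, seq, config.read_noise)
            d = seq_counts.setdefault(seq, {})
            for s, c in counts_per_tip[t].items():
                d[s] = d.get(s, 0) + c
            seq_mcs.setdefault(seq, set()).add(tree.mc_of_tip[t])

        asv_ids, sequences, true_mc = [], {}, {}
        data = {}
        for k, seq in enumerate(sorted(seq_counts)):
            if sum(seq_counts[seq].values()) == 0:
                continue
            asv = f"{marker}_ASV{k + 1:03d}"
            asv_ids.append(asv)
            sequences[asv] = seq
            mcs_here = seq_mcs[seq]
            true_mc[asv] = next(iter(mcs_here)) if len(mcs_here) == 1 else "ambiguous"
            data[asv] = [seq_counts[seq].get(s, 0) for s in metadata.index]
        counts = pd.DataFrame.from_dict(
            data, orient="index", columns=list(metadata.index), dtype=np.int64
        )
        table = AsvTable(counts=counts, sequences=sequences, marker=marker,
                         true_mc_of_asv=true_mc)
        table.validate()
        tables[marker] = table
    return tables


def _noisy_variant(rng: np.random.Generator, seq: str, noise: float) -> str:
    arr = np.array([("ACGT").index(c) for c in seq])
    hit = rng.random(arr.size) < noise
    if hit.any():
        arr[hit] = (arr[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return _to_str(arr)


# ---------------------------------------------------------------------------
# gene presence/absence


def simulate_gene_pa(tree: PopulationLabeledTree, config: SimulationConfig) -> GenePAMatrix:
    """Two-state gain/loss Markov chain per gene along the tree.

    Planted genes get a gain-rate multiplier (and loss divisor) on branches
    whose entire descendant tip set is specialist, producing genes whose
    presence associates with specialist status.
    """
    if config.gene_gain_rate <= 0 or config.gene_loss_rate <= 0:
        raise ValueError("gene gain/loss rates must be > 0")
    rng = child_rng(config.seed, "gene_pa")
    tips = sorted(t.name for t in tree.tree.tips())
    spec_tips = {t for t in tips if tree.is_specialist_tip(t)}

    # nodes whose descendant tips are all specialist
    all_spec: dict[int, bool] = {}
    for node in tree.tree.postorder(include_self=True):
        if node.is_tip():
            all_spec[id(node)] = node.name in spec_tips
        else:
            all_spec[id(node)] = all(all_spec[id(c)] for c in node.children)

    g, l = config.gene_gain_rate, config.gene_loss_rate
    genes = [f"OG{j + 1:04d}" for j in range(config.n_genes)]
    planted = set(genes[: config.n_planted_genes])

    def flip_prob(state: int, gain: float, loss: float, t: float) -> float:
        # two-state CTMC: P(0->1) and P(1->0) over branch length t
        tot = gain + loss
        decay = 1.0 - np.exp(-tot * t)
        return (gain / tot) * decay if state == 0 else (loss / tot) * decay

    data = {}
    invariant = set()
    for gene in genes:
        bias = config.planted_gene_bias if gene in planted else 1.0
        root_state = int(rng.random() < g / (g + l))
        states: dict[int, int] = {id(tree.tree): root_state}
        tip_states: dict[str, int] = {}
        for node in tree.tree.preorder(include_self=False):
            gain = g * (bias if all_spec[id(node)] else 1.0)
            loss = l / (bias if all_spec[id(node)] else 1.0)
            t = node.length or 0.0
            parent_state = states[id(node.parent)]
            if rng.random() < flip_prob(parent_state, gain, loss, t):
                state = 1 - parent_state
            else:
                state = parent_state
            states[id(node)] = state
            if node.is_tip():
                tip_states[node.name] = state
        col = [tip_states[t] for t in tips]
        if len(set(col)) == 1:
            invariant.add(gene)
        data[gene] = col
    table = pd.DataFrame(data, index=tips, dtype=np.int8)
    return GenePAMatrix(table=table, planted_genes=planted, invariant_genes=invariant)


# ---------------------------------------------------------------------------
# phenotypes


def simulate_rates(
    tree: PopulationLabeledTree,
    config: SimulationConfig,
    *,
    log_scale: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Brownian trait on the tree plus `specialist_rate_shift` at specialist tips."""
    if config.bm_rate <= 0:
        raise ValueError("bm_rate must be > 0")
    if rng is None:
        rng = child_rng(config.seed, "rates")
    sigma = float(np.sqrt(config.bm_rate))
    values: dict[int, float] = {id(tree.tree): 0.0}
    tip_vals: dict[str, float] = {}
    for node in tree.tree.preorder(include_self=False):
        t = node.length or 0.0
        v = values[id(node.parent)] + rng.normal(0.0, sigma * np.sqrt(t))
        values[id(node)] = v
        if node.is_tip():
            tip_vals[node.name] = v
    s = pd.Series(tip_vals).sort_index()
    shift = pd.Series(
        {t: config.specialist_rate_shift if tree.is_specialist_tip(t) else 0.0 for t in s.index}
    )
    s = s + shift
    if log_scale:
        s = np.exp(s)
    return s
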