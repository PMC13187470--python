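"""asv_assignment tests: profile alignment, joint NJ tree, the >80% rule."""

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from popspec.assign import (
    AssignmentResult,
    JointAlignment,
    JointTree,
    aggregate_population_abundance,
    align_queries_to_reference,
    assign_all,
    assign_asv_to_population,
    build_joint_tree,
)
from popspec.simulate import (
    SimulationConfig,
    make_metadata,
    simulate_asv_tables,
    simulate_marker_alignments,
    simulate_population_tree,
)
from conftest import random_tree, tree_from_newick


def _ref(n=5, L=60, seed=0, divergence=0.1):
    """Reference rows: mutated copies of one base sequence (a real profile)."""
    rng = np.random.default_rng(seed)
    base = rng.integers(0, 4, L)
    bases = np.array(list("ACGT"))
    rows = []
    for _ in range(n):
        row = base.copy()
        hit = rng.random(L) < divergence
        row[hit] = (row[hit] + rng.integers(1, 4, hit.sum())) % 4
        rows.append("".join(bases[row]))
    ids = [f"ref{i}" for i in range(n)]
    return ids, rows


class TestAlignQueries:
    def test_identical_query_reproduces_row(self):
        ids, rows = _ref()
        joint = align_queries_to_reference(ids, rows, {"q1": rows[0]})
        assert joint.rows[joint.ids.index("q1")] == rows[0]

    def test_single_substitution_same_columns(self):
        ids, rows = _ref()
        q = rows[0][:10] + ("A" if rows[0][10] != "A" else "C") + rows[0][11:]
        joint = align_queries_to_reference(ids, rows, {"q1": q})
        placed = joint.rows[joint.ids.index("q1")]
        diffs = [i for i, (a, b) in enumerate(zip(placed, rows[0])) if a != b]
        assert diffs == [10]

    def test_low_identity_excluded(self):
        ids, rows = _ref()
        junk = "A" * len(rows[0])
        joint = align_queries_to_reference(ids, rows, {"junk": junk})
        assert "junk" in joint.excluded_queries
        assert "junk" not in joint.ids

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            align_queries_to_reference([], [], {"q": "ACGT"})

    def test_simulated_asvs_recover_columns(self):
        cfg = SimulationConfig(n_populations=5, isolates_per_population=4,
                               n_specialists=2, read_noise=0.01, seed=9)
        tree = simulate_population_tree(cfg)
        alns = simulate_marker_alignments(tree, cfg)
        tables = simulate_asv_tables(tree, make_metadata(cfg), cfg, alns)
        aln = alns["taxonomic_1"]
        ref_ids = [i for i in aln.ids if aln.group_of_row[i] == "ingroup"]
        ref_rows = [r for i, r in zip(aln.ids, aln.rows)
                    if aln.group_of_row[i] == "ingroup"]
        seqs = tables["taxonomic_1"].sequences
        joint = align_queries_to_reference(ref_ids, ref_rows, seqs)
        # ungapped reference: correct placement means the row equals the query
        ok = sum(joint.rows[joint.ids.index(q)] == seqs[q]
                 for q in seqs if q in joint.ids)
        assert ok / len(seqs) >= 0.99


class TestJointTree:
    def _joint(self, ids, rows):
        kind = {i: ("reference" if i.startswith("r") else "query") for i in ids}
        return JointAlignment(ids=ids, rows=rows, kind=kind)

    def test_nj_recovers_additive_topology(self):
        # two clearly separated pairs
        rows = ["AAAAAAAAAAAAAAAAAAAA", "AAAAAAAAAAAAAAAAAAAC",
                "TTTTTTTTTTTTTTTTTTTT", "TTTTTTTTTTTTTTTTTGTT"]
        ids = ["r1", "r2", "r3", "r4"]
        jt = build_joint_tree(self._joint(ids, rows), {i: "MC1" for i in ids})
        t = jt.tree
        pair = {x.name for x in t.lca(["r1", "r2"]).tips()}
        assert pair == {"r1", "r2"} or pair == {"r1", "r2", "r3", "r4"} - {"r3", "r4"}

    def test_shuffled_rows_identical_newick(self):
        ids, rows = _ref(6, 80, seed=3)
        mc = {i: "MC1" for i in ids}
        a = build_joint_tree(self._joint(ids, rows), mc)
        order = [4, 2, 0, 5, 1, 3]
        b = build_joint_tree(
            self._joint([ids[i] for i in order], [rows[i] for i in order]), mc
        )
        assert str(a.tree) == str(b.tree)

    def test_duplicate_names_error(self):
        ids, rows = _ref(4)
        ids[1] = ids[0]
        with pytest.raises(ValueError):
            build_joint_tree(self._joint(ids, rows), {i: "MC1" for i in ids})

    def test_too_few_sequences(self):
        ids, rows = _ref(3)
        with pytest.raises(ValueError):
            build_joint_tree(self._joint(ids, rows), {i: "MC1" for i in ids})

    def test_simulated_mcs_mostly_monophyletic(self):
        from popspec.markers import score_population_resolution
        cfg = SimulationConfig(n_populations=5, isolates_per_population=4,
                               n_specialists=2, seed=13)
        tree = simulate_population_tree(cfg)
        alns = simulate_marker_alignments(tree, cfg)
        aln = alns["taxonomic_1"]
        ref_ids = [i for i in aln.ids if aln.group_of_row[i] == "ingroup"]
        ref_rows = [r for i, r in zip(aln.ids, aln.rows)
                    if aln.group_of_row[i] == "ingroup"]
        kind = {i: "reference" for i in ref_ids}
        jt = build_joint_tree(
            JointAlignment(ids=ref_ids, rows=ref_rows, kind=kind), aln.mc_of_row
        )
        score = score_population_resolution(jt.tree, aln.mc_of_row)
        assert score.fraction_monophyletic >= 0.9


def _joint_tree_from_newick(nwk, mc_of_ref, queries):
    tree = tree_from_newick(nwk)
    kind = {}
    for t in tree.tips():
        kind[t.name] = "query" if t.name in queries else "reference"
    return JointTree(tree=tree, tip_kind=kind, mc_of_reference=mc_of_ref)


def brute_force_assign(jt: JointTree, asv_id: str, tau: float = 0.8):
    """Independent oracle: enumerate descendant sets from scratch."""
    tip = next(t for t in jt.tree.tips() if t.name == asv_id)
    node, depth = tip.parent, 0
    while node is not None:
        refs = [t.name for t in node.tips()
                if jt.tip_kind.get(t.name) == "reference"]
        if refs:
            break
        node, depth = node.parent, depth + 1
    if node is None:
        return None, 0.0, 0, depth
    from collections import Counter
    counts = Counter(jt.mc_of_reference[r] for r in refs)
    (mc, c), *rest = counts.most_common()
    frac = c / len(refs)
    tied = rest and rest[0][1] == c
    return (mc if (frac > tau and not tied) else None), frac, len(refs), depth


class TestAssignmentRule:
    def test_pure_parent(self):
        nwk = "((q:1,(a:1,b:1,c:1,d:1,e:1):1):1,(x:1,y:1):1):0;"
        mc = {c: "MC6" for c in "abcde"} | {"x": "MC1", "y": "MC1"}
        jt = _joint_tree_from_newick(nwk, mc, {"q"})
        res = assign_asv_to_population(jt, "q")
        assert res.assigned_mc == "MC6" and res.supporting_fraction == 1.0
        assert res.ancestor_depth_used == 0

    def test_exact_080_boundary_unassigned(self):
        nwk = "((q:1,(a:1,b:1,c:1,d:1,e:1):1):1,(x:1,y:1):1):0;"
        mc = {"a": "MC1", "b": "MC1", "c": "MC1", "d": "MC1", "e": "MC3",
              "x": "MC2", "y": "MC2"}
        jt = _joint_tree_from_newick(nwk, mc, {"q"})
        res = assign_asv_to_population(jt, "q")
        assert res.assigned_mc is None
        assert res.supporting_fraction == pytest.approx(0.8)

    def test_nine_to_one_assigned(self):
        leaves = ",".join(f"a{i}:1" for i in range(9)) + ",b:1"
        nwk = f"((q:1,({leaves}):1):1,(x:1,y:1):1):0;"
        mc = {f"a{i}": "MC1" for i in range(9)} | {"b": "MC3", "x": "MC2", "y": "MC2"}
        jt = _joint_tree_from_newick(nwk, mc, {"q"})
        res = assign_asv_to_population(jt, "q")
        assert res.assigned_mc == "MC1"
        assert res.supporting_fraction == pytest.approx(0.9)

    def test_ascends_past_query_only_parent(self):
        nwk = "(((q:1,p:1):1,(a:1,b:1):1):1,(x:1,y:1):1):0;"
        mc = {"a": "MC1", "b": "MC1", "x": "MC2", "y": "MC2"}
        jt = _joint_tree_from_newick(nwk, mc, {"q", "p"})
        res = assign_asv_to_population(jt, "q")
        assert res.ancestor_depth_used == 1
        assert res.assigned_mc == "MC1"

    def test_reference_tip_errors(self):
        nwk = "((q:1,a:1):1,(b:1,c:1):1):0;"
        jt = _joint_tree_from_newick(nwk, {c: "MC1" for c in "abc"}, {"q"})
        with pytest.raises(ValueError):
            assign_asv_to_population(jt, "a")
        with pytest.raises(ValueError):
            assign_asv_to_population(jt, "nope")

    def test_random_trees_match_oracle(self, rng):
        for rep in range(60):
            n = int(rng.integers(6, 30))
            names = [f"t{i}" for i in range(n)]
            tree = random_tree(rng, names)
            queries = set(rng.choice(names, size=max(1, n // 4), replace=False))
            mc = {t: f"MC{rng.integers(4) + 1}" for t in names if t not in queries}
            kind = {t: ("query" if t in queries else "reference") for t in names}
            jt = JointTree(tree=tree, tip_kind=kind, mc_of_reference=mc)
            for q in sorted(queries):
                res = assign_asv_to_population(jt, q)
                exp_mc, exp_frac, exp_n, exp_depth = brute_force_assign(jt, q)
                assert res.assigned_mc == exp_mc
                assert res.supporting_fraction == pytest.approx(exp_frac)
                assert res.n_reference_tips_considered == exp_n
                assert res.ancestor_depth_used == exp_depth

    def test_rerooting_off_path_invariance(self, rng):
        for rep in range(20):
            n = 12
            names = [f"t{i}" for i in range(n)]
            tree = random_tree(rng, names)
            q = names[0]
            mc = {t: f"MC{rng.integers(3) + 1}" for t in names[1:]}
            kind = {t: ("query" if t == q else "reference") for t in names}
            jt = JointTree(tree=tree, tip_kind=kind, mc_of_reference=mc)
            res = assign_asv_to_population(jt, q)
            # path from q's used ancestor down: rerooting at a far tip's edge
            # that is outside the query clade should not change the call
            used = next(t for t in jt.tree.tips() if t.name == q).parent
            clade = {t.name for t in used.tips()}
            outside = [t for t in names[1:] if t not in clade]
            if not outside:
                continue
            copy = tree.copy()
            rerooted = copy.root_at(
                next(t for t in copy.tips() if t.name == outside[0]).parent
            )
            jt2 = JointTree(tree=rerooted, tip_kind=kind, mc_of_reference=mc)
            res2 = assign_asv_to_population(jt2, q)
            assert res2.assigned_mc == res.assigned_mc


class TestAggregate:
    def _assignments(self, mapping):
        return [AssignmentResult(a, mc, 1.0, 5, 0) for a, mc in mapping.items()]

    def test_basic_proportions(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["a", "b"])
        rel, unassigned, flagged = aggregate_population_abundance(
            counts, self._assignments({"a": "MC1", "b": "MC2"})
        )
        assert rel.loc["MC1", "s1"] == pytest.approx(0.25)
        assert rel.loc["MC2", "s1"] == pytest.approx(0.75)
        assert not flagged

    def test_all_unassigned_flagged(self):
        counts = pd.DataFrame({"s1": [10, 30]}, index=["a", "b"])
        rel, unassigned, flagged = aggregate_population_abundance(
            counts, self._assignments({"a": None, "b": None})
        )
        assert flagged == ["s1"]
        assert unassigned["s1"] == pytest.approx(1.0)

    def test_missing_record_errors(self):
        counts = pd.DataFrame({"s1": [10]}, index=["a"])
        with pytest.raises(ValueError):
            aggregate_population_abundance(counts, [])

    def test_columns_sum_to_one(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(6, 4)),
            index=list("abcdef"), columns=[f"s{i}" for i in range(4)],
        )
        counts.iloc[0] += 1  # ensure nonzero
        mapping = {a: f"MC{(i % 3) + 1}" for i, a in enumerate(counts.index)}
        rel, _, flagged = aggregate_population_abundance(counts, self._assignments(mapping))
        for s in rel.columns:
            if s not in flagged:
                assert rel[s].sum() == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery_matches_generator(self):
        cfg = SimulationConfig(n_populations=5, isolates_per_population=4,
                               n_specialists=2, seed=29)
        tree = simulate_population_tree(cfg)
        alns = simulate_marker_alignments(tree, cfg)
        tables = simulate_asv_tables(tree, make_metadata(cfg), cfg, alns)
        tab = tables["taxonomic_1"]
        # perfect assignment from ground truth
        res = [AssignmentResult(a, m if m != "ambiguous" else None, 1.0, 5, 0)
               for a, m in tab.true_mc_of_asv.items()]
        rel, _, _ = aggregate_population_abundance(tab.counts, res)
        # compare against generating per-MC proportions among unambiguous reads
        truth = {}
        for mc in tree.mcs:
            asvs = [a for a, m in tab.true_mc_of_asv.items() if m == mc]
            truth[mc] = tab.counts.loc[asvs].sum(axis=0)
        truth_df = pd.DataFrame(truth).T
        truth_rel = truth_df / truth_df.sum(axis=0)
        pd.testing.assert_frame_equal(
            rel.sort_index(), truth_rel.sort_index(), check_like=True
        )
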