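"""Trees, Kendall-Colijn comparison, delineation, taxonomy, genome stats."""

import itertools

import numpy as np
import pytest
from skbio import TreeNode

from pskit.records import DistanceMatrix, GenomeRecord
from pskit.treekit import (
    concat_core_distance,
    delineate_genomovars,
    forms_clade,
    genome_stats,
    kc_distance,
    kc_null_test,
    kc_vector,
    membership_screen,
    nj_tree,
    random_rooted_tree,
    taxonomy_report,
)

from conftest import random_genome


def zero_diag(labels, values):
    return DistanceMatrix(labels, np.asarray(values, dtype=float), "p_distance")


class TestNJ:
    def test_three_taxon_closed_form(self):
        # d(ab)=5 d(ac)=9 d(bc)=10 -> a=(5+9-10)/2=2, b=3, c=7
        m = zero_diag(list("abc"), [[0, 5, 9], [5, 0, 10], [9, 10, 0]])
        tree = nj_tree(m)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_five_taxon_additive_recovery(self):
        # random binary tree with known branch lengths -> NJ recovers the
        # tree exactly (additivity oracle: identical path-length matrices)
        rng = np.random.default_rng(11)
        true = random_rooted_tree(list("abcde"), rng)
        for node in true.traverse():
            if node.length is not None:
                node.length = float(rng.uniform(0.5, 3.0))
        labels = sorted(t.name for t in true.tips())
        tt = true.tip_tip_distances(labels)
        m = zero_diag(labels, tt.data)
        recovered = nj_tree(m)
        rec = recovered.tip_tip_distances(labels)
        assert np.allclose(rec.data, tt.data, atol=1e-9)

    def test_genomovars_form_clades_in_ani_tree(self, small_dataset, small_matrices):
        tree = nj_tree(small_matrices["ani"].transform("ani_dist"))
        labels = small_dataset.truth.true_genomovar_labels
        for gv in set(labels.values()):
            assert forms_clade(tree, {g for g, v in labels.items() if v == gv})

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(zero_diag(list("ab"), [[0, 1], [1, 0]]))


class TestConcatCore:
    def test_identical_sequences_zero_matrix(self):
        seqs = {"f1": {"a": "ACGTACGT", "b": "ACGTACGT"}}
        m = concat_core_distance(seqs)
        assert m["a", "b"] == 0.0

    def test_site_count_oracle(self):
        # 12 mismatches over 1200 concatenated sites -> p-distance 0.01
        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        seq = "".join(bases[rng.integers(0, 4, 1200)])
        arr = list(seq)
        pos = rng.choice(1200, 12, replace=False)
        for p in pos:
            arr[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[arr[p]]
        other = "".join(arr)
        seqs = {
            "f1": {"a": seq[:700], "b": other[:700]},
            "f2": {"a": seq[700:], "b": other[700:]},
        }
        m = concat_core_distance(seqs)
        assert m["a", "b"] == pytest.approx(0.01)

    def test_no_core_families_is_an_error(self):
        with pytest.raises(ValueError):
            concat_core_distance({})


class TestKendallColijn:
    def test_hand_enumerated_four_leaf_vectors(self):
        bal = TreeNode.read(["((a:1,b:1):1,(c:1,d:1):1);"])
        cat = TreeNode.read(["(((a:1,b:1):1,c:1):1,d:1);"])
        # pairs in sorted order: ab ac ad bc bd cd
        assert kc_vector(bal).tolist() == [1, 0, 0, 0, 0, 1]
        assert kc_vector(cat).tolist() == [2, 1, 0, 1, 0, 0]
        assert kc_distance(bal, cat) == pytest.approx(np.sqrt(1 + 1 + 0 + 1 + 0 + 1))
        assert kc_distance(bal, bal) == 0.0
        assert kc_distance(cat, bal) == kc_distance(bal, cat)

    def test_metric_axioms_on_random_topologies(self):
        rng = np.random.default_rng(13)
        trees = [random_rooted_tree(list("abcde"), rng) for _ in range(6)]
        for t1, t2, t3 in itertools.combinations(trees, 3):
            d12, d23, d13 = kc_distance(t1, t2), kc_distance(t2, t3), kc_distance(t1, t3)
            assert d13 <= d12 + d23 + 1e-12
            assert d12 >= 0

    def test_leaf_set_mismatch_rejected(self):
        t1 = TreeNode.read(["((a:1,b:1):1,c:1);"])
        t2 = TreeNode.read(["((a:1,b:1):1,d:1);"])
        with pytest.raises(ValueError):
            kc_distance(t1, t2)

    def test_null_test_identical_trees_significant(self):
        rng = np.random.default_rng(14)
        t = random_rooted_tree([f"g{i}" for i in range(10)], rng)
        res = kc_null_test(t, t, n_random=300, seed=1)
        assert res.distance == 0.0
        assert res.p_value < 0.05

    def test_null_calibration_rejection_rate(self):
        # a random query against a random reference: the z-test should
        # reject at roughly its nominal rate
        rng = np.random.default_rng(15)
        leaves = [f"g{i}" for i in range(8)]
        reject = 0
        n_rep = 150
        for rep in range(n_rep):
            q = random_rooted_tree(leaves, rng)
            ref = random_rooted_tree(leaves, rng)
            res = kc_null_test(q, ref, n_random=150, seed=1000 + rep)
            reject += res.p_value < 0.05
        rate = reject / n_rep
        assert 0.0 <= rate <= 0.12

    def test_small_null_rejected(self):
        t = TreeNode.read(["((a:1,b:1):1,c:1);"])
        with pytest.raises(ValueError):
            kc_null_test(t, t, n_random=50)


class TestDelineation:
    def borderline(self, ani_ab, ddh_ab):
        labels = ["s1", "s2"]
        ani = DistanceMatrix(labels, [[100, ani_ab], [ani_ab, 100]], "ani")
        ddh = DistanceMatrix(labels, [[100, ddh_ab], [ddh_ab, 100]], "ddh")
        return ani, ddh

    def test_borderline_pair_joined_under_defaults(self):
        # the canonical near-threshold conspecific pair: ANI 94.89 / dDDH 59.9
        ani, ddh = self.borderline(94.89, 59.9)
        assert delineate_genomovars(ani, ddh).n_genomovars == 1

    def test_borderline_pair_split_at_strict_cutoffs(self):
        ani, ddh = self.borderline(94.89, 59.9)
        assert delineate_genomovars(ani, ddh, ani_t=95.0, ddh_t=60.0).n_genomovars == 2

    def test_high_ani_single_genomovar(self):
        labels = [f"g{i}" for i in range(4)]
        vals = np.full((4, 4), 99.0)
        np.fill_diagonal(vals, 100.0)
        ani = DistanceMatrix(labels, vals, "ani")
        ddh = DistanceMatrix(labels, np.where(vals < 100, 90.0, 100.0), "ddh")
        assert delineate_genomovars(ani, ddh).n_genomovars == 1

    def test_components_match_transitive_closure_oracle(self):
        rng = np.random.default_rng(16)
        n = 12
        labels = [f"g{i:02d}" for i in range(n)]
        ani_vals = rng.uniform(90, 100, (n, n))
        ani_vals = (ani_vals + ani_vals.T) / 2
        np.fill_diagonal(ani_vals, 100.0)
        ddh_vals = np.full((n, n), 99.0)
        ani = DistanceMatrix(labels, ani_vals, "ani")
        ddh = DistanceMatrix(labels, ddh_vals, "ddh")
        assign = delineate_genomovars(ani, ddh, ani_t=94.5, ddh_t=59.5)
        # brute-force transitive closure
        adj = {a: set() for a in labels}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j and ani_vals[i, j] >= 94.5:
                    adj[a].add(b)
        seen, comps = set(), []
        for a in labels:
            if a in seen:
                continue
            stack, comp = [a], set()
            while stack:
                x = stack.pop()
                if x in comp:
                    continue
                comp.add(x)
                stack.extend(adj[x] - comp)
            seen |= comp
            comps.append(frozenset(comp))
        ours = {}
        for g, gv in assign.assignment.items():
            ours.setdefault(gv, set()).add(g)
        assert set(map(frozenset, ours.values())) == set(comps)

    def test_extreme_thresholds(self):
        labels = [f"g{i}" for i in range(5)]
        vals = np.full((5, 5), 92.0)
        np.fill_diagonal(vals, 100.0)
        ani = DistanceMatrix(labels, vals, "ani")
        ddh = DistanceMatrix(labels, vals, "ddh")
        assert delineate_genomovars(ani, ddh, 0.0, 0.0).n_genomovars == 1
        assert delineate_genomovars(ani, ddh, 100.1, 100.1).n_genomovars == 5


class TestTaxonomy:
    def test_all_consistent(self):
        from pskit.treekit import GenomovarAssignment

        assign = GenomovarAssignment({"a": "gv1", "b": "gv1"}, 94.5, 59.5)
        rep = taxonomy_report(assign, {"a": "sp_x", "b": "sp_x"}, {"gv1": "sp_x"})
        assert rep.counts == {"consistent": 2}

    def test_planted_wrong_label_flagged(self):
        from pskit.treekit import GenomovarAssignment

        assign = GenomovarAssignment(
            {"a": "gv1", "b": "gv1", "c": "gv2"}, 94.5, 59.5
        )
        rep = taxonomy_report(
            assign,
            {"a": "sp_x", "b": "sp_y", "c": "sp_y"},
            {"gv1": "sp_x", "gv2": "sp_y"},
        )
        verdicts = dict(zip(rep.table.genome, rep.table.verdict))
        assert verdicts == {"a": "consistent", "b": "misidentified", "c": "consistent"}

    def test_unnamed_component_is_novel_genomovar(self):
        from pskit.treekit import GenomovarAssignment

        assign = GenomovarAssignment({"a": "gv1", "b": "gv1"}, 94.5, 59.5)
        rep = taxonomy_report(assign, {"a": "sp.", "b": "sp."}, {})
        assert set(rep.table.verdict) == {"novel_genomovar"}


class TestMembershipScreen:
    def test_screen_separates_members_from_outgroup(self, small_dataset):
        from dataclasses import replace

        from pskit.synthio import SimConfig, simulate

        from conftest import diverged_relative

        # an unrelated random genome: fails the ANI prefilter outright
        out_cfg = SimConfig(n_genomovars=1, genomes_per_genomovar=1,
                            root_families=60, accessory_pool=0, seed=77)
        unrelated = replace(simulate(out_cfg).genomes[0], genome_id="unrelated")
        # a diverged relative: passes the >= 80% ANI prefilter yet branches
        # basally, outside the smallest clade spanned by the references
        relative = diverged_relative(
            small_dataset.genome("gv3_g2"), 0.18, seed=5, new_id="relative"
        )
        refs = [
            small_dataset.genome("gv1_g1"),
            small_dataset.genome("gv2_g2"),
            small_dataset.genome("gv3_g1"),
        ]
        candidates = [small_dataset.genome("gv1_g2"), relative, unrelated]
        members = membership_screen(candidates, refs, prefilter_ani=80.0)
        assert "gv1_g2" in members
        assert "unrelated" not in members
        assert "relative" not in members

    def test_candidate_identical_to_reference_is_member(self, small_dataset):
        ref = small_dataset.genome("gv1_g1")
        twin = GenomeRecord("twin", dict(ref.contigs), list(ref.genes))
        members = membership_screen([twin], [ref], prefilter_ani=80.0)
        assert members == ["twin"]


class TestGenomeStats:
    def test_gc_of_atgc(self):
        g = GenomeRecord("toy", {"c": "ATGC"})
        stats = genome_stats([g])
        assert stats.table.gc_percent.iloc[0] == pytest.approx(50.0)

    def test_gc_matches_direct_counting(self):
        g = random_genome("g", 10_000, seed=17)
        seq = next(iter(g.contigs.values()))
        expected = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        assert genome_stats([g]).table.gc_percent.iloc[0] == pytest.approx(expected)

    def test_two_group_gc_difference_detected(self):
        rng = np.random.default_rng(18)

        def gc_genome(name, gc):
            probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
            seq = "".join(np.array(list("AGCT"))[rng.choice(4, 10_000, p=probs)])
            return GenomeRecord(name, {"c": seq})

        genomes = [gc_genome(f"lo{i}", 0.55) for i in range(5)] + [
            gc_genome(f"hi{i}", 0.63) for i in range(5)
        ]
        groups = {g.genome_id: ("low" if g.genome_id.startswith("lo") else "high")
                  for g in genomes}
        stats = genome_stats(genomes, groups)
        assert stats.gc_test is not None
        assert stats.gc_test[1] < 0.01
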