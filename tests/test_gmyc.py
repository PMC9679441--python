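import math

import dendropy
import numpy as np
import pytest

from coipipe import gmyc, synthetic
from coipipe.gmyc import GMYCParams, UltrametricityError


def interval_oracle(tree, T, params):
    """Brute-force interval-by-interval likelihood.

    Scans the tree from the tips upward maintaining explicit lineage sets,
    recomputing per-interval rates directly from the model definition:
    rate = lambda_div * k**p_div + lambda_coal * sum_j (m_j(m_j-1))**p_coal,
    event term = its process class's rate.  Independent of the package's
    sufficient-statistics path.
    """
    ld, pd_, lc, pc = params.lambda_div, params.p_div, params.lambda_coal, params.p_coal
    entities = gmyc.delimit(tree, T)
    cluster_of = {tip: ci for ci, ent in enumerate(entities) for tip in ent}
    k_cross = 0 if T >= tree.root_height else len(entities)

    # nodes ascending by height with their descendant tip sets
    children = {}
    for i, p in enumerate(tree.parent):
        if p >= 0:
            children.setdefault(int(p), []).append(i)

    def tips_under(i):
        if i < tree.n_tips:
            return {tree.tip_labels[i]}
        out = set()
        for c in children[i]:
            out |= tips_under(c)
        return out

    internals = sorted(range(tree.n_tips, len(tree.parent)),
                       key=lambda i: tree.event_index[i])
    active = [{lb} for lb in tree.tip_labels]
    ll, prev_h = 0.0, 0.0
    for node in internals:
        h = float(tree.height[node])
        x = h - prev_h
        m = {}
        for lin in active:
            cs = {cluster_of[t] for t in lin}
            if len(cs) == 1:
                c = cs.pop()
                m[c] = m.get(c, 0) + 1
        coal_sum = sum((mm * (mm - 1)) ** pc for mm in m.values() if mm >= 2)
        if h <= T:
            rate = (ld * k_cross**pd_ if k_cross else 0.0) + lc * coal_sum
            r_event = lc * coal_sum
        else:
            N = len(active)
            rate = ld * N**pd_
            r_event = rate
        ll += math.log(r_event) - rate * x
        merged = tips_under(node)
        active = [lin for lin in active if not lin <= merged] + [merged]
        prev_h = h
    return ll


@pytest.fixture
def balanced3():
    return gmyc.parse_newick("((a:1,b:1):1,c:2);")


class TestTreeParsing:
    def test_ultrametric_tree_heights(self, balanced3):
        assert balanced3.root_height == pytest.approx(2.0)
        assert balanced3.n_tips == 3
        assert sorted(balanced3.tip_labels) == ["a", "b", "c"]

    def test_non_ultrametric_rejected(self):
        # tips a and c fall short of the deepest root-to-tip path (via b)
        with pytest.raises(UltrametricityError, match="violate"):
            gmyc.parse_newick("((a:1,b:2):1,c:2);")

    def test_violation_report_names_short_tips(self):
        tree = dendropy.Tree.get(data="((a:1,b:2):1,c:3);", schema="newick")
        report = gmyc.validate_ultrametric(tree)
        assert [t for t, _ in report] == ["a"]

    def test_underscored_labels_preserved(self):
        tree = gmyc.parse_newick("((sp1_t1:1,sp1_t2:1):1,sp2_t1:2);")
        assert "sp1_t1" in tree.tip_labels

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_simulated_trees_validate(self, seed):
        newick, _ = synthetic.generate_tree(synthetic.TreeSpec(seed=seed))
        tree = gmyc.parse_newick(newick, tol=1e-9)
        assert tree.n_tips == 30


class TestBranchingTimes:
    def test_two_tip_tree(self):
        tree = gmyc.parse_newick("(a:1.5,b:1.5);")
        assert tree.branching_times() == pytest.approx([1.5])

    def test_three_tip_example(self, balanced3):
        assert balanced3.branching_times() == pytest.approx([2.0, 1.0])

    def test_matches_independent_traversal(self):
        newick, _ = synthetic.generate_tree(synthetic.TreeSpec(seed=4))
        tree = gmyc.parse_newick(newick)
        dtree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        dtree.calc_node_root_distances(return_leaf_distances_only=False)
        dmax = max(lf.root_distance for lf in dtree.leaf_node_iter())
        ages = sorted(
            dmax - nd.root_distance
            for nd in dtree.preorder_node_iter()
            if not nd.is_leaf()
        )
        assert tree.branching_times() == pytest.approx(ages[::-1], abs=1e-9)


class TestDelimit:
    def test_threshold_at_root_single_entity(self, balanced3):
        entities = gmyc.delimit(balanced3, 2.0)
        assert entities == (("a", "b", "c"),)

    def test_threshold_below_all_nodes_all_singletons(self, balanced3):
        assert gmyc.delimit(balanced3, 0.0) == (("a",), ("b",), ("c",))

    def test_intermediate_cut(self, balanced3):
        assert gmyc.delimit(balanced3, 1.5) == (("a", "b"), ("c",))

    def test_entities_partition_tips_and_shrink_with_T(self):
        newick, _ = synthetic.generate_tree(synthetic.TreeSpec(seed=6))
        tree = gmyc.parse_newick(newick)
        prev = None
        for T in np.linspace(0, tree.root_height, 12):
            ents = gmyc.delimit(tree, T)
            tips = sorted(t for e in ents for t in e)
            assert tips == sorted(tree.tip_labels)
            if prev is not None:
                assert len(ents) <= prev
            prev = len(ents)


class TestLoglik:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_interval_oracle_on_small_trees(self, seed):
        rng = np.random.default_rng(seed)
        newick, _ = synthetic.generate_tree(
            synthetic.TreeSpec(n_species=2, tips_per_species=3, seed=seed)
        )
        tree = gmyc.parse_newick(newick)
        params = GMYCParams(
            float(rng.uniform(0.2, 3)), float(rng.uniform(0, 2)),
            float(rng.uniform(0.2, 3)), float(rng.uniform(0, 2)),
        )
        for T in [0.0, tree.event_heights[2] * 1.01, tree.root_height]:
            assert gmyc.gmyc_loglik(tree, T, params) == pytest.approx(
                interval_oracle(tree, T, params), abs=1e-9
            )

    def test_five_tip_worked_tree(self):
        tree = gmyc.parse_newick(
            "(((a:0.1,b:0.1):0.9,(c:0.2,d:0.2):0.8):1.0,e:2.0);"
        )
        params = GMYCParams(0.8, 1.0, 3.0, 1.0)
        T = 0.5  # clusters {a,b}, {c,d}, {e}
        # hand computation over the 4 intervals (heights 0.1, 0.2, 1.0, 2.0):
        # i1 [0,0.1]: k=3, m={ab:2, cd:2}; coal_sum=2+2=4
        #   r=0.8*3+3*4=14.4, event coal in ab: r_event=12
        # i2 [0.1,0.2]: m={cd:2}; coal_sum=2; r=2.4+6=8.4, event coal: r_event=6
        # i3 [0.2,1.0]: coal done; r=0.8*3=2.4, div event: r_event=2.4
        # i4 [1.0,2.0]: N=2; r=1.6, div event: r_event=1.6
        expected = (
            (math.log(12.0) - 14.4 * 0.1)
            + (math.log(6.0) - 8.4 * 0.1)
            + (math.log(2.4) - 2.4 * 0.8)
            + (math.log(1.6) - 1.6 * 1.0)
        )
        assert gmyc.gmyc_loglik(tree, T, params) == pytest.approx(expected, abs=1e-12)

    def test_collapse_to_null_at_root(self):
        newick, _ = synthetic.generate_tree(synthetic.TreeSpec(seed=8))
        tree = gmyc.parse_newick(newick)
        params = GMYCParams(0.7, 1.3, 2.0, 0.9)
        ll = gmyc.gmyc_loglik(tree, tree.root_height, params)
        null = gmyc._null_stats(tree).loglik(params.lambda_coal, params.p_coal)
        assert ll == pytest.approx(null, abs=1e-9)

    def test_invalid_threshold_or_rates_rejected(self, balanced3):
        params = GMYCParams(1.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            gmyc.gmyc_loglik(balanced3, 3.0, params)
        with pytest.raises(ValueError):
            GMYCParams(-1.0, 1.0, 1.0, 1.0)


class TestFitNull:
    def test_two_tip_closed_form(self):
        t = 0.8
        tree = gmyc.parse_newick(f"(a:{t},b:{t});")
        (lam, p), ll = gmyc.fit_null(tree)
        # single interval: L(lam, p) = 2^p lam exp(-2^p lam t); the profile
        # logL is -log t - 1 for every p, and at p=1 lambda_hat = 1/(2t)
        assert ll == pytest.approx(-math.log(t) - 1.0, abs=1e-9)
        assert lam * 2**p == pytest.approx(1.0 / t, rel=1e-6)
        (lam1, _), _ = gmyc.fit_null(tree, fix_p=1.0)
        assert lam1 == pytest.approx(1.0 / (2 * t), rel=1e-9)

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_null_never_beats_gmyc(self, seed):
        newick, _ = synthetic.generate_tree(synthetic.TreeSpec(seed=seed))
        tree = gmyc.parse_newick(newick)
        fit = gmyc.fit_single_threshold(tree)
        assert fit.logL_gmyc >= fit.logL_null - 1e-9
        assert fit.LR >= 0


class TestFitSingleThreshold:
    def test_recovers_known_species_partition(self):
        newick, membership = synthetic.generate_tree(synthetic.TreeSpec(seed=12))
        tree = gmyc.parse_newick(newick)
        fit = gmyc.fit_single_threshold(tree)
        truth = {
            tuple(sorted(membership[membership.species == s]["tip"]))
            for s in membership.species.unique()
        }
        assert fit.n_species == 5
        assert set(fit.entities) == truth

    def test_yule_only_tree_keeps_tips_separate(self):
        # every tip its own species: fitted threshold near zero
        newick, _ = synthetic.generate_tree(
            synthetic.TreeSpec(n_species=25, tips_per_species=1, seed=2)
        )
        tree = gmyc.parse_newick(newick)
        fit = gmyc.fit_single_threshold(tree)
        assert fit.n_species >= 0.9 * tree.n_tips

    def test_self_consistency_of_reported_likelihood(self):
        newick, _ = synthetic.generate_tree(synthetic.TreeSpec(seed=13))
        tree = gmyc.parse_newick(newick)
        fit = gmyc.fit_single_threshold(tree)
        recomputed = gmyc.gmyc_loglik(tree, fit.threshold_time, fit.params)
        assert fit.logL_gmyc == pytest.approx(recomputed, abs=1e-8)
        assert fit.n_species == len(fit.clusters) + len(fit.singletons)

    def test_too_few_tips_rejected(self):
        tree = gmyc.parse_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="3 tips"):
            gmyc.fit_single_threshold(tree)


class TestParameterRecovery:
    def test_coalescent_rate_recovered_on_large_trees(self):
        """On 200-tip trees with a known within-species rate, the fitted
        coalescent rate (exponent fixed at the generating value 1) has
        median relative error below 25%."""
        errors = []
        for seed in range(20):
            spec = synthetic.TreeSpec(n_species=5, tips_per_species=40, seed=seed)
            newick, membership = synthetic.generate_tree(spec)
            tree = gmyc.parse_newick(newick)
            truth = {
                tuple(sorted(membership[membership.species == s]["tip"]))
                for s in membership.species.unique()
            }
            T_true = next(
                T for T in gmyc._candidate_thresholds(tree)
                if set(gmyc.delimit(tree, T)) == truth
            )
            # reconstruct the generating pairwise rate from the tree
            min_div = tree.event_heights[tree.event_heights > T_true].min()
            m = spec.tips_per_species
            pair_rate = 2.0 * (1 - 1 / m) / (min_div / spec.depth_ratio)
            lam_true = pair_rate / 2.0
            params, _ = gmyc.fit_at_threshold(tree, T_true, fix_p_div=1.0, fix_p_coal=1.0)
            errors.append(abs(params.lambda_coal - lam_true) / lam_true)
        assert float(np.median(errors)) < 0.25
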