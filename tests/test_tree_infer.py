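"""Models, distances, NJ, gamma, likelihood, search, MCMC, support."""

import itertools
import math

import numpy as np
import pytest
from scipy import integrate, linalg, stats

import dendropy

from sirphylo.io_core import PhyloTree, TreeNode, ValidationError, parse_newick, write_newick
from sirphylo.msa import MultipleAlignment
from sirphylo.tree_infer import (
    DistanceMatrix,
    annotate_consensus_support,
    bayesian_mcmc,
    default_candidates,
    discrete_gamma_rates,
    load_model,
    log_likelihood,
    ml_pairwise_distance,
    ml_search,
    neighbor_joining,
    optimize_branch_lengths,
    robinson_foulds,
    select_model,
    spr_neighbors,
)
from conftest import (
    AA,
    additive_distances,
    all_unrooted_topologies,
    random_binary_tree,
    simulate_alignment,
)


def exhaustive_log_likelihood(tree, aln, model):
    """Sum over all internal-node state assignments, transition matrices
    from an independent matrix exponential (scipy.linalg.expm)."""
    pi = model.stationary_frequencies
    Q = model.rate_matrix
    rates = model.rates()
    internals = [n for n in tree.postorder() if not n.is_leaf]
    leaves = {n.name: n for n in tree.leaves()}
    row = {rid: aln.rows[i] for i, rid in enumerate(aln.row_ids)}
    lnl = 0.0
    for col in range(aln.n_columns):
        site_like = 0.0
        for rate in rates:
            P = {id(n): linalg.expm(Q * (n.length * rate))
                 for n in tree.postorder() if n is not tree.root}
            total = 0.0
            for states in itertools.product(range(20), repeat=len(internals)):
                smap = {id(n): s for n, s in zip(internals, states)}
                for name, node in leaves.items():
                    c = row[name][col]
                    smap[id(node)] = AA.index(c) if c in AA else None
                term = pi[smap[id(tree.root)]]
                ok = True
                for node in tree.postorder():
                    if node is tree.root:
                        continue
                    child_state = smap[id(node)]
                    if child_state is None:
                        continue  # missing data: sums to 1, handled below
                    term *= P[id(node)][smap[id(node.parent)], child_state]
                total += term
            site_like += total / len(rates)
        lnl += math.log(site_like)
    return lnl


class TestSubstitutionModel:
    @pytest.mark.parametrize("name", ["WAG", "DAYHOFF"])
    def test_generator_invariants(self, name):
        m = load_model(name)
        q = m.rate_matrix
        assert np.allclose(q.sum(axis=1), 0, atol=1e-12)
        mu = -float(np.dot(m.stationary_frequencies, np.diag(q)))
        assert mu == pytest.approx(1.0, abs=1e-10)
        assert np.all(m.stationary_frequencies > 0)

    def test_transition_matrix_matches_expm(self):
        m = load_model("WAG")
        for t in (0.01, 0.3, 2.0):
            assert np.allclose(
                m.transition_matrix(t), linalg.expm(m.rate_matrix * t), atol=1e-10
            )

    def test_detailed_balance(self):
        m = load_model("DAYHOFF")
        pi = m.stationary_frequencies
        flux = pi[:, None] * m.rate_matrix
        assert np.allclose(flux, flux.T, atol=1e-12)


class TestMlPairwiseDistance:
    def test_identical_rows_give_zero(self):
        aln = MultipleAlignment(["a", "b"], ["MKVILQ", "MKVILQ"])
        dm = ml_pairwise_distance(aln, load_model("DAYHOFF"))
        assert dm.values[0, 1] <= 1e-7

    def test_recovers_simulated_distance(self, rng):
        """Length-1000 pairs at true distance 0.3: estimate within 0.05,
        20 replicates."""
        model = load_model("DAYHOFF")
        errors = []
        for _ in range(20):
            a = rng.choice(20, 1000, p=model.stationary_frequencies)
            P = model.transition_matrix(0.3)
            cum = P[a].cumsum(axis=1)
            b = (rng.random(1000)[:, None] > cum).sum(axis=1)
            aln = MultipleAlignment(
                ["x", "y"],
                ["".join(AA[i] for i in a), "".join(AA[i] for i in b)],
            )
            d = ml_pairwise_distance(aln, model).values[0, 1]
            errors.append(abs(d - 0.3))
        assert np.median(errors) < 0.05
        assert max(errors) < 0.15

    def test_unrelated_sequences_saturate_at_cap(self, rng):
        model = load_model("DAYHOFF")
        a = rng.choice(20, 400, p=model.stationary_frequencies)
        b = rng.choice(20, 400, p=model.stationary_frequencies)
        aln = MultipleAlignment(
            ["x", "y"], ["".join(AA[i] for i in a), "".join(AA[i] for i in b)]
        )
        dm = ml_pairwise_distance(aln, model, d_max=10.0)
        assert dm.values[0, 1] == pytest.approx(10.0)
        assert dm.saturated[0, 1]

    def test_no_shared_columns_names_pair(self):
        aln = MultipleAlignment(["a", "b"], ["M-", "-K"])
        with pytest.raises(ValidationError, match="'a'.*'b'"):
            ml_pairwise_distance(aln, load_model("DAYHOFF"))


class TestNeighborJoining:
    def test_three_point_formula(self):
        dm = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        )
        tree = neighbor_joining(dm)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 2.0}

    def test_additive_matrix_recovered_exactly(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            gen = random_binary_tree([f"T{i}" for i in range(n)], rng)
            names, D = additive_distances(gen)
            tree = neighbor_joining(DistanceMatrix(names, D))
            assert robinson_foulds(tree, gen) == 0
            names2, D2 = additive_distances(tree)
            order = [names2.index(x) for x in names]
            assert np.allclose(D, D2[np.ix_(order, order)], atol=1e-9)

    def test_equal_distances_deterministic_tie_break(self):
        labels = ["d", "c", "b", "a"]
        D = np.ones((4, 4)) - np.eye(4)
        t1 = neighbor_joining(DistanceMatrix(labels, D.copy()))
        t2 = neighbor_joining(DistanceMatrix(labels, D.copy()))
        assert write_newick(t1, "none") == write_newick(t2, "none")
        # smallest label pair (a, b) must be joined first
        joined = {
            frozenset(l.name for l in n.leaves())
            for n in t1.postorder()
            if not n.is_leaf and n is not t1.root
        }
        assert frozenset({"a", "b"}) in joined

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValidationError):
            neighbor_joining(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestDiscreteGamma:
    def test_single_category_is_one(self):
        assert discrete_gamma_rates(0.7, 1).tolist() == [1.0]

    @pytest.mark.parametrize("alpha", [0.1, 0.5, 1.0, 5.0, 1e6])
    @pytest.mark.parametrize("k", [1, 4, 8])
    def test_mean_is_exactly_one(self, alpha, k):
        rates = discrete_gamma_rates(alpha, k)
        assert rates.mean() == pytest.approx(1.0, abs=1e-10)

    def test_huge_alpha_degenerates_to_uniform(self):
        # deviations shrink as Theta(1/sqrt(alpha)); for k=4 the outer
        # category means sit at 1 +/- 4*phi(z_0.75)/sqrt(alpha) ~ 1.27e-3
        rates = discrete_gamma_rates(1e6, 4)
        assert np.allclose(rates, 1.0, atol=2e-3)
        assert np.allclose(discrete_gamma_rates(1e8, 4), 1.0, atol=2e-4)

    def test_matches_quadrature_oracle(self):
        alpha, k = 0.5, 4
        rates = discrete_gamma_rates(alpha, k)
        dist = stats.gamma(a=alpha, scale=1 / alpha)
        bounds = [0] + list(dist.ppf(np.arange(1, k) / k)) + [np.inf]
        for i in range(k):
            val, _ = integrate.quad(
                lambda x: x * dist.pdf(x), bounds[i], bounds[i + 1]
            )
            assert rates[i] == pytest.approx(k * val, abs=1e-6)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValidationError):
            discrete_gamma_rates(0.0, 4)


class TestLogLikelihood:
    def test_zero_branch_two_leaves_is_log_pi(self):
        model = load_model("WAG")
        root = TreeNode(children=[TreeNode("a", length=0.0), TreeNode("b", length=0.0)])
        tree = PhyloTree(root)
        aln = MultipleAlignment(["a", "b"], ["A", "A"])
        assert log_likelihood(tree, aln, model) == pytest.approx(
            math.log(model.stationary_frequencies[0])
        )

    def test_two_leaf_closed_form(self):
        model = load_model("WAG")
        t = 0.37
        root = TreeNode(children=[TreeNode("a", length=t), TreeNode("b", length=0.0)])
        tree = PhyloTree(root)
        aln = MultipleAlignment(["a", "b"], ["M", "K"])
        P = linalg.expm(model.rate_matrix * t)
        i, j = AA.index("M"), AA.index("K")
        expect = math.log(model.stationary_frequencies[j] * P[j, i])
        assert log_likelihood(tree, aln, model) == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("alpha", [None, 0.6])
    def test_matches_exhaustive_state_sum(self, rng, alpha):
        """Pruning equals brute-force summation over internal states on a
        4-leaf tree (400 terms per site), with and without gamma."""
        model = load_model("WAG", alpha=alpha)
        tree = random_binary_tree(["a", "b", "c", "d"], rng)
        aln = simulate_alignment(tree, load_model("WAG"), 5, rng)
        got = log_likelihood(tree, aln, model)
        expect = exhaustive_log_likelihood(tree, aln, model)
        assert got == pytest.approx(expect, abs=1e-8)

    def test_gap_is_missing_data(self):
        """A column that is gap in one row contributes that row's marginal:
        lnL of (A, -) equals lnL of the single-leaf marginal = log pi_A."""
        model = load_model("WAG")
        root = TreeNode(children=[TreeNode("a", length=0.2), TreeNode("b", length=0.2)])
        tree = PhyloTree(root)
        aln = MultipleAlignment(["a", "b"], ["AM", "-M"])
        full = log_likelihood(tree, aln, model)
        aln_m = MultipleAlignment(["a", "b"], ["M", "M"])
        only_m = log_likelihood(tree, aln_m, model)
        assert full == pytest.approx(
            only_m + math.log(model.stationary_frequencies[0]), abs=1e-10
        )

    def test_label_mismatch_lists_difference(self):
        model = load_model("WAG")
        root = TreeNode(children=[TreeNode("a", length=0.1), TreeNode("z", length=0.1)])
        aln = MultipleAlignment(["a", "b"], ["M", "M"])
        with pytest.raises(ValidationError, match="z.*b|b.*z"):
            log_likelihood(PhyloTree(root), aln, model)


class TestMlSearch:
    def test_three_leaves_unique_topology(self, rng):
        model = load_model("WAG")
        tree = random_binary_tree(["a", "b", "c"], rng)
        aln = simulate_alignment(tree, model, 100, rng)
        out, lnl = ml_search(aln, model)
        assert set(out.leaf_names()) == {"a", "b", "c"}
        start = out.copy()
        assert lnl >= log_likelihood(start, aln, model) - 1e-9

    def test_four_leaves_matches_exhaustive_enumeration(self, rng):
        """SPR hill-climb finds the same topology as scoring all 3
        topologies with per-topology branch-length optimization."""
        model = load_model("WAG")
        true = parse_newick("((a:0.3,b:0.3):0.15,(c:0.3,d:0.3):0.15);")
        aln = simulate_alignment(true, model, 200, rng)
        found, found_lnl = ml_search(aln, model)
        best_lnl, best = -np.inf, None
        for cand in all_unrooted_topologies(["a", "b", "c", "d"]):
            lnl = optimize_branch_lengths(cand, aln, model)
            if lnl > best_lnl:
                best_lnl, best = lnl, cand
        assert robinson_foulds(found, best) == 0
        assert found_lnl == pytest.approx(best_lnl, abs=1e-3)

    def test_spr_neighborhood_size(self):
        tree = parse_newick("((A:1,B:1):1,C:1,(D:1,E:1):1);")
        # 2(n-3)(2n-7) = 12 distinct SPR neighbors for n = 5
        assert len(spr_neighbors(tree)) == 12

    def test_recovers_true_six_taxon_topology(self, rng):
        """Simulation under WAG+G with long sequences: true topology
        recovered (RF = 0) in most of 6 replicates."""
        model = load_model("WAG", alpha=0.8)
        hits = 0
        for _ in range(6):
            true = random_binary_tree(
                [f"t{i}" for i in range(6)], rng, blen=(0.1, 0.4)
            )
            aln = simulate_alignment(true, load_model("WAG"), 500, rng, alpha=0.8)
            found, _ = ml_search(aln, model)
            hits += robinson_foulds(found, true) == 0
        assert hits >= 5


class TestSelectModel:
    def test_single_candidate_returned(self, rng):
        model = load_model("WAG")
        tree = random_binary_tree(["a", "b", "c", "d"], rng)
        aln = simulate_alignment(tree, model, 50, rng)
        best, table = select_model(aln, [model])
        assert best.name == "WAG" and len(table) == 1

    def test_bic_prefers_fewer_parameters_on_tie(self):
        """The gamma model cannot beat uniform on perfectly uniform data by
        more than the BIC penalty; uniform (fewer parameters) must win."""
        model = load_model("WAG")
        rng = np.random.default_rng(7)
        tree = random_binary_tree(["a", "b", "c", "d"], rng, blen=(0.2, 0.3))
        aln = simulate_alignment(tree, model, 300, rng)
        best, table = select_model(
            aln, [load_model("WAG"), load_model("WAG", alpha=1.0)]
        )
        assert best.alpha is None

    def test_recovers_gamma_model(self, rng):
        """Data simulated under WAG+G(alpha=0.4), 500 columns: WAG+G
        selected over the uniform and Dayhoff candidates (5 replicates)."""
        hits = 0
        for _ in range(5):
            tree = random_binary_tree(
                [f"t{i}" for i in range(5)], rng, blen=(0.15, 0.5)
            )
            aln = simulate_alignment(tree, load_model("WAG"), 500, rng, alpha=0.4)
            best, _ = select_model(aln, default_candidates())
            hits += best.name == "WAG" and best.alpha is not None
        assert hits >= 4

    def test_empty_candidates_rejected(self, rng):
        tree = random_binary_tree(["a", "b", "c"], rng)
        aln = simulate_alignment(tree, load_model("WAG"), 10, rng)
        with pytest.raises(ValidationError):
            select_model(aln, [])


class TestBayesianMcmc:
    def test_three_leaves_unique_topology_posterior_one(self, rng):
        model = load_model("WAG")
        tree = random_binary_tree(["a", "b", "c"], rng)
        aln = simulate_alignment(tree, model, 60, rng)
        res = bayesian_mcmc(aln, model, generations=1000, sample_every=10, seed=3)
        assert set(res.consensus.leaf_names()) == {"a", "b", "c"}
        assert res.consensus.bipartitions() == set()

    def test_burnin_arithmetic(self, rng):
        """1000 retained samples at burn-in 0.25 -> consensus from 750."""
        model = load_model("WAG")
        tree = random_binary_tree(["a", "b", "c"], rng)
        aln = simulate_alignment(tree, model, 30, rng)
        res = bayesian_mcmc(
            aln, model, generations=10000, sample_every=10,
            burnin_fraction=0.25, seed=1,
        )
        assert res.n_samples == 1000
        assert res.n_retained == 750

    def test_seed_reproducibility(self, rng):
        model = load_model("WAG")
        tree = random_binary_tree(["a", "b", "c", "d"], rng)
        aln = simulate_alignment(tree, model, 80, rng)
        r1 = bayesian_mcmc(aln, model, generations=1500, seed=11)
        r2 = bayesian_mcmc(aln, model, generations=1500, seed=11)
        assert [t["lnL"] for t in r1.trace] == [t["lnL"] for t in r2.trace]
        assert write_newick(r1.consensus, "numeric") == write_newick(
            r2.consensus, "numeric"
        )

    def test_concentrated_posterior_matches_ml_topology(self, rng):
        """On clean 4-leaf data the consensus equals the ML topology and
        the acceptance rate is strictly between 0 and 1."""
        model = load_model("WAG")
        true = parse_newick("((a:0.3,b:0.3):0.2,(c:0.3,d:0.3):0.2);")
        aln = simulate_alignment(true, model, 300, rng)
        res = bayesian_mcmc(aln, model, generations=4000, sample_every=10, seed=2)
        assert 0.0 < res.acceptance_rate < 1.0
        assert robinson_foulds(res.consensus, true) == 0
        split = next(iter(res.consensus.bipartitions()))
        assert res.split_posteriors[split] > 0.95

    def test_posterior_branch_length_tracks_ml(self, rng):
        """Posterior mean tree length within 3 Monte-Carlo SE of the ML
        estimate on a fixed topology (near-flat prior regime)."""
        model = load_model("WAG")
        true = parse_newick("((a:0.2,b:0.2):0.1,(c:0.2,d:0.2):0.1);")
        aln = simulate_alignment(true, model, 400, rng)
        ml_tree = true.copy()
        optimize_branch_lengths(ml_tree, aln, model)
        res = bayesian_mcmc(
            aln, model, generations=20000, sample_every=20,
            seed=4, start_tree=true,
        )
        lengths = np.array(
            [t["tree_length"] for t in res.trace[res.n_samples - res.n_retained:]]
        )
        # thinned samples still autocorrelated; inflate SE accordingly
        se = lengths.std() / math.sqrt(max(len(lengths) / 10.0, 1.0))
        assert abs(lengths.mean() - ml_tree.total_length()) < 3 * se + 0.02

    def test_invalid_generations_rejected(self, rng):
        model = load_model("WAG")
        tree = random_binary_tree(["a", "b", "c"], rng)
        aln = simulate_alignment(tree, model, 10, rng)
        with pytest.raises(ValidationError):
            bayesian_mcmc(aln, model, generations=0)


def dendropy_splits(trees):
    """Independent bipartition sets via dendropy."""
    tns = dendropy.TaxonNamespace()
    out = []
    for tree in trees:
        dt = dendropy.Tree.get(
            data=write_newick(tree, "none"), schema="newick",
            taxon_namespace=tns,
        )
        dt.encode_bipartitions()
        out.append(
            {
                b.split_bitmask
                for b in dt.bipartition_encoding
                if not b.is_trivial()
            }
        )
    return out


class TestSupportAnnotation:
    def test_identical_topologies_all_double_star(self, rng):
        tree = random_binary_tree([f"x{i}" for i in range(6)], rng)
        ann = annotate_consensus_support(tree, [tree.copy(), tree.copy()])
        counts = [
            n.support
            for n in ann.postorder()
            if not n.is_leaf and n is not ann.root and n.support is not None
        ]
        assert counts and all(c == 3 for c in counts)
        assert "**" in write_newick(ann, "stars")

    def test_unique_split_counts_one(self):
        primary = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        other1 = parse_newick("((A:1,C:1):1,(B:1,D:1):1);")
        other2 = parse_newick("((A:1,D:1):1,(B:1,C:1):1);")
        ann = annotate_consensus_support(primary, [other1, other2])
        supports = [n.support for n in ann.postorder() if n.support is not None]
        assert supports and all(s == 1 for s in supports)
        assert "*" not in write_newick(ann, "stars")

    def test_counts_match_bipartition_oracle(self, rng):
        """Algorithm counts equal an independent dendropy bipartition
        intersection on 20 random 8-leaf triples."""
        names = [f"t{i}" for i in range(8)]
        for _ in range(20):
            trees = [random_binary_tree(names, rng) for _ in range(3)]
            ann = annotate_consensus_support(trees[0], trees[1:])
            splits = dendropy_splits(trees)
            # count agreement per internal branch of the primary
            expected = {
                s: 1 + sum(s in o for o in splits[1:]) for s in splits[0]
            }
            got = sorted(
                n.support
                for n in ann.postorder()
                if n.support is not None
            )
            assert got == sorted(expected.values())

    def test_leaf_mismatch_rejected(self, rng):
        a = random_binary_tree(["a", "b", "c", "d"], rng)
        b = random_binary_tree(["a", "b", "c", "e"], rng)
        with pytest.raises(ValidationError, match="d|e"):
            annotate_consensus_support(a, [b, b.copy()])


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, rng):
        t = random_binary_tree([f"x{i}" for i in range(7)], rng)
        assert robinson_foulds(t, t.copy()) == 0

    def test_conflicting_quartets_distance_two(self):
        a = parse_newick("((A,B),(C,D));")
        b = parse_newick("((A,C),(B,D));")
        assert robinson_foulds(a, b) == 2

    def test_matches_dendropy(self, rng):
        names = [f"t{i}" for i in range(8)]
        tns = dendropy.TaxonNamespace()
        for _ in range(20):
            a = random_binary_tree(names, rng)
            b = random_binary_tree(names, rng)
            da = dendropy.Tree.get(data=write_newick(a, "none"),
                                   schema="newick", taxon_namespace=tns)
            db = dendropy.Tree.get(data=write_newick(b, "none"),
                                   schema="newick", taxon_namespace=tns)
            expect = dendropy.calculate.treecompare.symmetric_difference(da, db)
            assert robinson_foulds(a, b) == expect
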