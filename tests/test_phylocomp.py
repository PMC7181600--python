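"""Tree preparation, pFDA, Brownian ASR, juvenile substitution, proxies."""

import shutil
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest

from cranionet import (PhylogeneticFDA, asr_bm, consensus_edges,
                       juvenile_substitute, parsimony_proxies, pfda,
                       phylo_covariance, read_tree, simulate_bm_tree,
                       split_ontogenetic_tips)
from cranionet.phylocomp import tip_labels


def bf_gls_root(tree, values):
    """Independent GLS phylogenetic mean: (1'V^-1 x)/(1'V^-1 1).

    V is built here by direct root-to-tip traversal, without using the
    package's covariance helper.
    """
    leaves = list(tree.leaf_node_iter())

    def path_to_root(node):
        out = []
        while node.parent_node is not None:
            out.append(node)
            node = node.parent_node
        return out

    n = len(leaves)
    v = np.zeros((n, n))
    paths = [path_to_root(l) for l in leaves]
    for i in range(n):
        for j in range(n):
            shared = set(id(x) for x in paths[i]) & set(id(x) for x in paths[j])
            v[i, j] = sum(x.edge.length for x in paths[i] if id(x) in shared)
    x = np.array([values[l.taxon.label] for l in leaves])
    vinv = np.linalg.inv(v)
    one = np.ones(n)
    return (one @ vinv @ x) / (one @ vinv @ one)


class TestConsensusEdges:
    def test_identical_trees_pass_through(self):
        t = read_tree("((A:1,B:1):2,C:3);")
        out = consensus_edges([t, t.clone(depth=1)], t)
        assert (out.as_string(schema="newick", suppress_rooting=True)
                == t.as_string(schema="newick", suppress_rooting=True))

    def test_mean_of_two_lengths(self):
        t1 = read_tree("((A:1,B:1):2,C:3);")
        t2 = read_tree("((A:3,B:1):2,C:3);")
        out = consensus_edges([t1, t2], t1)
        lens = {l.taxon.label: l.edge.length for l in out.leaf_node_iter()}
        assert lens["A"] == pytest.approx(2.0)
        assert lens["B"] == pytest.approx(1.0)

    def test_mean_over_jittered_set(self):
        rng = np.random.default_rng(3)
        base = read_tree("(((A:1,B:1):1,C:2):1,D:3);")
        trees, truth = [], {}
        for _ in range(100):
            t = base.clone(depth=1)
            for e in t.preorder_edge_iter():
                if e.head_node.parent_node is None:
                    continue
                e.length = e.length + rng.normal(0, 0.01)
            trees.append(t)
        out = consensus_edges(trees, base)
        for leaf in out.leaf_node_iter():
            vals = []
            for t in trees:
                match = [l for l in t.leaf_node_iter()
                         if l.taxon.label == leaf.taxon.label][0]
                vals.append(match.edge.length)
            assert leaf.edge.length == pytest.approx(np.mean(vals), abs=1e-12)

    def test_idempotent_and_order_invariant(self):
        t1 = read_tree("((A:1,B:1):2,C:3);")
        t2 = read_tree("((A:3,B:2):2,C:1);")
        a = consensus_edges([t1, t2], t1)
        b = consensus_edges([t2, t1], t1)
        nwk = lambda t: t.as_string(schema="newick", suppress_rooting=True)
        assert nwk(a) == nwk(b)
        again = consensus_edges([a], t1)
        assert nwk(again) == nwk(a)

    def test_topology_mismatch_rejected(self):
        t1 = read_tree("((A:1,B:1):2,C:3);")
        t2 = read_tree("((A:1,C:1):2,B:3);")
        with pytest.raises(ValueError, match="split"):
            consensus_edges([t2], t1)


class TestSplitTips:
    def test_single_bird_tip_becomes_cherry(self):
        t = read_tree("((A:5,B:5):5,C:10);")
        out = split_ontogenetic_tips(t, ["A"], bird_bl=1.0)
        labels = set(tip_labels(out))
        assert labels == {"A_juv", "A_ad", "B", "C"}
        cherry = [l for l in out.leaf_node_iter() if l.taxon.label == "A_juv"][0]
        assert cherry.edge.length == pytest.approx(1.0)
        assert cherry.parent_node.edge.length == pytest.approx(4.0)

    def test_nonbird_uses_longer_pendant(self):
        t = read_tree("((A:5,B:5):5,Alligator:30);")
        out = split_ontogenetic_tips(t, ["Alligator"], nonbird={"Alligator"})
        juv = [l for l in out.leaf_node_iter()
               if l.taxon.label == "Alligator_juv"][0]
        assert juv.edge.length == pytest.approx(10.0)
        assert juv.parent_node.edge.length == pytest.approx(20.0)

    def test_splitting_every_tip_doubles_count(self):
        tree, _, _ = simulate_bm_tree(12, seed=1)
        species = tip_labels(tree)
        out = split_ontogenetic_tips(tree, species, bird_bl=1e-3)
        assert len(tip_labels(out)) == 24

    def test_unknown_species_rejected(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError):
            split_ontogenetic_tips(t, ["Z"])


class TestPhyloCovariance:
    def test_worked_three_taxon_tree(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        v = phylo_covariance(t, ["A", "B", "C"])
        expected = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        assert np.allclose(v.to_numpy(), expected)


class TestAsrBm:
    def test_worked_root_value(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        res = asr_bm(t, {"A": 0.0, "B": 0.0, "C": 3.0})
        assert res.root_value == pytest.approx(9 / 7, abs=1e-12)

    def test_constant_tips_reconstruct_constant(self):
        tree, _, _ = simulate_bm_tree(10, seed=5)
        res = asr_bm(tree, {t: 2.5 for t in tip_labels(tree)})
        assert all(v == pytest.approx(2.5, abs=1e-9)
                   for v in res.node_values.values())
        assert res.sd_proxy == pytest.approx(0.0, abs=1e-9)

    def test_root_matches_gls_closed_form_small_trees(self):
        for seed in range(8):
            tree, tips, _ = simulate_bm_tree(6, seed=seed)
            res = asr_bm(tree, tips)
            assert res.root_value == pytest.approx(bf_gls_root(tree, tips),
                                                   abs=1e-9)

    def test_root_within_tip_range_on_clock_trees(self):
        for seed in range(5):
            tree, tips, _ = simulate_bm_tree(15, seed=seed)
            res = asr_bm(tree, tips)
            assert min(tips.values()) <= res.root_value <= max(tips.values())

    def test_matches_ape_ace(self, tmp_path):
        """Cross-check every internal node against R's ape::ace (ML)."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        tree, tips, _ = simulate_bm_tree(10, seed=7)
        res = asr_bm(tree, tips)
        nwk = tmp_path / "t.nwk"
        nwk.write_text(tree.as_string(schema="newick", suppress_rooting=True))
        tipcsv = tmp_path / "tips.csv"
        pd.Series(tips).to_csv(tipcsv, header=False)
        script = tmp_path / "ace.R"
        script.write_text(f"""
            library(ape)
            tr <- read.tree("{nwk}")
            d <- read.csv("{tipcsv}", header=FALSE)
            x <- setNames(d$V2, d$V1)[tr$tip.label]
            a <- ace(x, tr, type="continuous", method="ML")
            write.csv(data.frame(v=as.numeric(a$ace)), "{tmp_path}/out.csv",
                      row.names=FALSE)
        """)
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        ape_vals = pd.read_csv(tmp_path / "out.csv")["v"].to_numpy()
        mine = np.array(sorted(res.node_values.values()))
        assert np.allclose(np.sort(ape_vals), mine, atol=1e-4)

    def test_missing_tip_value_rejected(self):
        t = read_tree("((A:1,B:1):1,C:2);")
        with pytest.raises(KeyError, match="C"):
            asr_bm(t, {"A": 0.0, "B": 1.0})

    def test_clade_values_at_mrca(self):
        t = read_tree("((A:1,B:1)AB:1,C:2);")
        res = asr_bm(t, {"A": 1.0, "B": 1.0, "C": 4.0},
                     clades={"inner": ["A", "B"], "all": ["A", "B", "C"]})
        assert res.clade_values["all"] == pytest.approx(res.root_value)
        assert res.clade_values["inner"] != res.clade_values["all"]


class TestPfda:
    def _star(self, n):
        nwk = "(" + ",".join(f"t{i}:1.0" for i in range(n)) + ");"
        return read_tree(nwk)

    def test_lambda_zero_on_star_equals_plain_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(11)
        tree = self._star(24)
        names = [f"t{i}" for i in range(24)]
        X = pd.DataFrame(rng.normal(size=(20, 2)), index=names[:20])
        y = np.array(["A"] * 10 + ["B"] * 10)
        X.iloc[:10] += 1.5
        test = pd.DataFrame(rng.normal(size=(4, 2)) + 0.75, index=names[20:])
        est = PhylogeneticFDA(tree, lambda_grid=[0.0]).fit(X, y)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        assert (est.predict(test).to_numpy() == lda.predict(test)).all()
        # confusion tables agree (leave-one-out on identically scaled data)
        assert est.confusion_.to_numpy().sum() == 20

    def test_perfect_separation(self):
        rng = np.random.default_rng(13)
        tree = self._star(20)
        names = [f"t{i}" for i in range(20)]
        X = pd.DataFrame(rng.normal(size=(16, 2)), index=names[:16])
        X.iloc[:8] += 10.0  # ten within-group SDs apart
        y = ["hi"] * 8 + ["lo"] * 8
        est = PhylogeneticFDA(tree, lambda_grid=[0.0, 0.5, 1.0]).fit(X, y)
        assert est.error_ == 0.0
        test = pd.DataFrame([[10.0, 10.0], [0.0, 0.0]], index=names[16:18])
        proba = est.predict_proba(test)
        assert proba.loc[names[16], "hi"] > 0.99
        assert proba.loc[names[17], "lo"] > 0.99
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_bm_shifted_groups_recovered_on_40_tip_tree(self):
        """Held-out tips are assigned to the right group >= 90% of the time."""
        hits = trials = 0
        for seed in range(4):
            tree, trait1, _ = simulate_bm_tree(40, seed=seed)
            _, trait2, _ = simulate_bm_tree(40, seed=1000 + seed)
            rng = np.random.default_rng(100 + seed)
            names = list(trait1)
            groups = pd.Series(["A"] * 20 + ["B"] * 20, index=names)
            X = pd.DataFrame({"x": pd.Series(trait1), "y": pd.Series(trait2)})
            X.loc[groups == "B", "x"] += 3 * X["x"].std()
            held = list(rng.choice(names, 8, replace=False))
            train = [t for t in names if t not in held]
            est = PhylogeneticFDA(tree, lambda_grid=np.arange(0, 1.01, 0.1))
            est.fit(X.loc[train], groups[train])
            pred = est.predict(X.loc[held])
            hits += int((pred == groups[held]).sum())
            trials += len(held)
        assert hits / trials >= 0.90

    def test_lambda_tie_breaks_small(self):
        rng = np.random.default_rng(17)
        tree = self._star(12)
        names = [f"t{i}" for i in range(12)]
        X = pd.DataFrame(rng.normal(size=(12, 1)), index=names)
        X.iloc[:6] += 20.0
        y = ["A"] * 6 + ["B"] * 6
        est = PhylogeneticFDA(tree, lambda_grid=[0.0, 0.3, 0.7]).fit(X, y)
        # perfect separation at every lambda -> tie -> smallest chosen
        assert est.lambda_ == 0.0

    def test_singular_within_group_covariance_rejected(self):
        tree = self._star(8)
        names = [f"t{i}" for i in range(8)]
        X = pd.DataFrame(np.ones((6, 3)), index=names[:6])  # rank-0 residuals
        with pytest.raises(ValueError, match="singular"):
            PhylogeneticFDA(tree, lambda_grid=[0.0]).fit(
                X, ["A", "A", "A", "B", "B", "B"])


class TestJuvenileSubstitution:
    def test_perfectly_linear_trait_collapses_to_anchor(self):
        sizes = pd.Series({"a": 10.0, "b": 20.0, "c": 40.0, "d": 5.0})
        traits = 3.0 + 0.5 * sizes
        adj = juvenile_substitute(traits, sizes, "d")
        assert np.allclose(adj, 3.0 + 0.5 * 5.0)

    def test_recovers_generator_hatchling_values(self):
        """Residual standardization recovers true hatchling values to noise."""
        rng = np.random.default_rng(19)
        n = 30
        hatchling = rng.normal(size=n)          # true value at minimum size
        sizes = pd.Series(rng.uniform(10, 80, size=n),
                          index=[f"s{i}" for i in range(n)])
        sizes.iloc[0] = 5.0                     # the youngest individual
        slope = 0.3
        noise_sd = 0.05
        traits = pd.Series(hatchling, index=sizes.index) \
            + slope * (sizes - 5.0) + rng.normal(0, noise_sd, n)
        adj = juvenile_substitute(traits, sizes, "s0")
        resid = adj - (pd.Series(hatchling, index=sizes.index)
                       + traits.mean() - traits.mean())
        # hatchling values recovered up to a common offset and the noise scale
        centered = (adj - adj.mean()) - (hatchling - hatchling.mean())
        assert centered.abs().mean() < 5 * noise_sd + 0.2

    def test_wrong_youngest_rejected(self):
        sizes = pd.Series({"a": 10.0, "b": 5.0})
        with pytest.raises(ValueError, match="minimum"):
            juvenile_substitute(pd.Series({"a": 1.0, "b": 2.0}), sizes, "a")

    def test_constant_sizes_rejected(self):
        sizes = pd.Series({"a": 5.0, "b": 5.0, "c": 5.0})
        traits = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        with pytest.raises(ValueError):
            juvenile_substitute(traits, sizes, "a")


class TestParsimonyProxies:
    def test_identical_reconstructions_differ_by_zero(self):
        tree, tips, _ = simulate_bm_tree(8, seed=23)
        a = asr_bm(tree, tips)
        cmp_ = parsimony_proxies(a, a)
        assert cmp_.sd_difference == 0.0

    def test_sd_proxy_is_sample_sd_of_node_values(self):
        tree, tips, _ = simulate_bm_tree(12, seed=29)
        res = asr_bm(tree, tips)
        vals = np.array(list(res.node_values.values()))
        assert res.sd_proxy == pytest.approx(np.std(vals, ddof=1), abs=1e-12)

    def test_smooth_trend_more_parsimonious_than_clade_jump(self):
        """A clade-localized jump in the adult values inflates the SD of the
        ancestral values relative to a smooth gradient (heterochrony signal)."""
        wins = 0
        n_seeds = 30
        for seed in range(n_seeds):
            tree, _, _ = simulate_bm_tree(24, seed=seed)
            tips = tip_labels(tree)
            rng = np.random.default_rng(500 + seed)
            # clade-localized shift: the largest non-trivial clade jumps
            internal = [n for n in tree.preorder_internal_node_iter()
                        if n is not tree.seed_node]
            # a clade of roughly half the tips carries the jump
            half = sorted(internal,
                          key=lambda n: abs(len(n.leaf_nodes()) - 12))[0]
            big = [l.taxon.label for l in half.leaf_nodes()]
            shifted = {t: (3.0 if t in big else 0.0) + rng.normal(0, 0.1)
                       for t in tips}
            smooth = {t: i / len(tips) + rng.normal(0, 0.1)
                      for i, t in enumerate(tips)}
            cmp_ = parsimony_proxies(asr_bm(tree, shifted),
                                     asr_bm(tree, smooth))
            wins += cmp_.sd_difference > 0
        assert wins / n_seeds >= 0.95
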