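"""Ancestral reconstruction against a direct joint-enumeration oracle, and
substitution mapping."""

import numpy as np
import pytest

import burstscan as bs
from burstscan.ancestry import (AncestralReconstruction, map_substitutions,
                                marginal_posteriors, prune_likelihood)
from burstscan.codon import CODON_INDEX, SENSE_CODONS
from burstscan.io import CodonAlignment, parse_newick
from burstscan.model import N_CODONS, CodonModel

from conftest import random_codons


def joint_enumeration(tree, site, model, query_node=None):
    """Independent oracle: the likelihood as a direct sum of the joint
    probability over all internal-node state assignments, written as one
    tensor contraction of the factorised joint (prior x per-edge transition
    matrices x leaf indicators).  With ``query_node`` the sum leaves that
    node's index free, giving the unnormalised marginal."""
    import string

    idx = {n: string.ascii_letters[n] for n in range(tree.n_nodes)}
    operands, script = [], []
    script.append(idx[tree.root])
    operands.append(model.freqs)
    for child in tree.edges:
        t = model.ds_to_subs_per_codon(tree.edge_length(child))
        operands.append(model.transition_matrix(t))
        script.append(idx[tree.parent[child]] + idx[child])
    for leaf in tree.leaves:
        codon = site[tree.labels[leaf]]
        vec = np.zeros(N_CODONS)
        i = CODON_INDEX.get(codon)
        if i is None:
            vec[:] = 1.0
        else:
            vec[i] = 1.0
        operands.append(vec)
        script.append(idx[leaf])
    out = "" if query_node is None else idx[query_node]
    return np.einsum(",".join(script) + "->" + out, *operands,
                     optimize="greedy")


TOPOLOGIES = [
    "(A:{a},B:{b})r;",
    "((A:{a},B:{b})x:{c},C:{d})r;",
    "((A:{a},B:{b})x:{c},(C:{d},D:{e})y:{f})r;",
    "(((A:{a},B:{b})x:{c},C:{d})y:{e},D:{f})r;",
    "(((A:{a},B:{b})x:{c},(C:{d},D:{e})y:{f})z:{g},E:{h})r;",
]


def random_instance(seed, topology):
    rng = np.random.default_rng(seed)
    lens = {k: float(rng.uniform(0.01, 0.3))
            for k in "abcdefgh"}
    tree = parse_newick(topology.format(**lens))
    model = CodonModel(kappa=float(rng.uniform(1.0, 4.0)),
                       omega=float(rng.uniform(0.2, 2.0)))
    site = dict(zip(tree.leaf_names,
                    random_codons(rng, len(tree.leaf_names))))
    return tree, model, site


@pytest.mark.parametrize("topology", TOPOLOGIES)
@pytest.mark.parametrize("seed", [1, 2, 3])
def test_pruning_matches_joint_enumeration(topology, seed):
    tree, model, site = random_instance(seed, topology)
    got = prune_likelihood(tree, site, model)
    want = joint_enumeration(tree, site, model)
    assert got == pytest.approx(want, rel=1e-10)


@pytest.mark.parametrize("topology", TOPOLOGIES[2:])
@pytest.mark.parametrize("seed", [11, 12])
def test_posteriors_match_joint_enumeration(topology, seed):
    tree, model, site = random_instance(seed, topology)
    aln = CodonAlignment("g", {t: site[t] for t in tree.leaf_names})
    rec = marginal_posteriors(tree, aln, model, keep_posteriors=True)
    for r, node in enumerate(rec.internal_nodes):
        marg = joint_enumeration(tree, site, model, query_node=node)
        marg = marg / marg.sum()
        assert np.allclose(rec.posteriors[r, 0], marg, atol=1e-10)


def test_zero_length_limits(neutral_model):
    tree = parse_newick("(A:0.0,B:0.0)r;")
    like = prune_likelihood(tree, {"A": "TTT", "B": "TTT"}, neutral_model)
    assert like == pytest.approx(neutral_model.freqs[CODON_INDEX["TTT"]])

    star = parse_newick("(A:0.0,B:0.0,C:0.0,D:0.0)r;")
    aln = CodonAlignment("g", {t: "TTT" for t in "ABCD"})
    rec = marginal_posteriors(star, aln, neutral_model)
    assert rec.map_codon(0, 0) == "TTT"
    assert rec.posterior_of_map(0, 0) == pytest.approx(1.0)


def test_independence_limit(neutral_model):
    tree = parse_newick("(A:400.0,B:400.0)r;")
    like = prune_likelihood(tree, {"A": "TTT", "B": "ATG"}, neutral_model)
    pi = neutral_model.freqs
    want = pi[CODON_INDEX["TTT"]] * pi[CODON_INDEX["ATG"]]
    assert like == pytest.approx(want, rel=1e-6)


def test_posteriors_sum_to_one(small_dataset, gammarid_tree, neutral_model):
    gene = small_dataset.genes["g0003"]
    aln = gene.alignment(gammarid_tree)
    rec = marginal_posteriors(gammarid_tree, aln, neutral_model,
                              keep_posteriors=True)
    sums = rec.posteriors.sum(axis=2)
    assert np.allclose(sums, 1.0, atol=1e-9)
    assert np.all(rec.map_posterior >= 1.0 / N_CODONS - 1e-12)


def test_map_recovers_simulated_ancestors(small_dataset, gammarid_tree,
                                          neutral_model):
    """At clade-like divergence the MAP state matches the true simulated
    ancestral codon at >= 95% of sites."""
    correct = total = 0
    for gid in ["g0001", "g0002", "g0003"]:
        gene = small_dataset.genes[gid]
        aln = gene.alignment(gammarid_tree)
        rec = marginal_posteriors(gammarid_tree, aln, neutral_model)
        for r, node in enumerate(rec.internal_nodes):
            truth = gene.node_states[node]
            correct += int((rec.map_state[r] == truth).sum())
            total += truth.shape[0]
    assert correct / total >= 0.95


class TestMapSubstitutions:
    @pytest.fixture()
    def cherry(self):
        tree = parse_newick("((A:0.01,B:0.01)x:0.004,(C:0.01,D:0.01)y:0.01)r;")
        aln = CodonAlignment("g", {"A": "TTC", "B": "TTT", "C": "TTT",
                                   "D": "TTT"})
        return tree, aln

    def make_rec(self, tree, aln, posts):
        """Hand-built reconstruction: all internal MAPs TTT with given MAP
        posteriors per internal node label."""
        internal = tree.internal_nodes
        state = np.full((len(internal), aln.n_codons), CODON_INDEX["TTT"],
                        dtype=np.int16)
        post = np.ones((len(internal), aln.n_codons))
        for i, node in enumerate(internal):
            post[i, :] = posts.get(tree.labels[node], 1.0)
        return AncestralReconstruction(tree, internal, state, post,
                                       frozenset())

    def test_leaf_edge_event(self, cherry):
        tree, aln = cherry
        rec = self.make_rec(tree, aln, {})
        m = map_substitutions(rec, aln, tree.node("A"), 0.8)
        assert len(m.events) == 1
        ev = m.events[0]
        assert (ev.parent_codon, ev.child_codon) == ("TTT", "TTC")
        assert (ev.nd, ev.sd) == (0.0, 1.0)

    def test_low_posterior_site_excluded(self, cherry):
        tree, aln = cherry
        rec = self.make_rec(tree, aln, {"x": 0.79})
        m = map_substitutions(rec, aln, tree.node("A"), 0.8)
        assert m.events == []
        assert m.excluded_columns == frozenset({0})

    def test_multistep_path_averaging(self):
        tree = parse_newick("((A:0.01,B:0.01)x:0.004,C:0.01)r;")
        aln = CodonAlignment("g", {"A": "GTA", "B": "GTA", "C": "TTT"})
        internal = tree.internal_nodes
        state = np.array([[CODON_INDEX["TTT"]], [CODON_INDEX["GTA"]]],
                         dtype=np.int16)
        rec = AncestralReconstruction(tree, internal, state,
                                      np.ones((2, 1)), frozenset())
        m = map_substitutions(rec, aln, tree.node("x"), 0.8)
        assert m.events[0].nd == pytest.approx(1.5)
        assert m.events[0].sd == pytest.approx(0.5)

    def test_min_posterior_monotonicity(self, small_dataset, gammarid_tree,
                                        neutral_model):
        gene = small_dataset.genes["g0005"]
        aln = gene.alignment(gammarid_tree)
        rec = marginal_posteriors(gammarid_tree, aln, neutral_model)
        edge = gammarid_tree.node("n2")
        counts = [len(map_substitutions(rec, aln, edge, thr).events)
                  for thr in (0.0, 0.5, 0.8, 0.95, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_invalid_threshold(self, cherry):
        tree, aln = cherry
        rec = self.make_rec(tree, aln, {})
        with pytest.raises(ValueError):
            map_substitutions(rec, aln, tree.node("A"), 1.5)
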