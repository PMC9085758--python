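"""Entity graphs, reactor semantics, and network generation."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesocell.entities import (BindingSite, ComplexEntity, Condition,
                               NetworkGenerationError, ReactionRule, Reactor,
                               RuleDefinitionError, SimpleEntity,
                               apply_reactor, generate_network)


def make_simples(*names, small=(), membrane=()):
    return {n: SimpleEntity(n, small_molecule=n in small,
                            membrane_bound=n in membrane) for n in names}


def complex_from(simples, nodes, edges):
    g = nx.Graph()
    for k, name in enumerate(nodes):
        g.add_node(k, entity=name)
    for u, v, site in edges:
        g.add_edge(u, v, site=site)
    return ComplexEntity(g, simples)


# ---------------------------------------------------------------------------
# Reactor semantics
# ---------------------------------------------------------------------------

class TestReactors:
    def setup_method(self):
        self.simples = make_simples("PKAR", "PKAC", "cAMP", "AQP2", "P",
                                    small=("cAMP", "P"))
        self.sites = {s.name: s for s in [
            BindingSite("B", ("PKAR", "cAMP")),
            BindingSite("A", ("PKAR", "cAMP")),
            BindingSite("rc", ("PKAR", "PKAC")),
            BindingSite("s256", ("AQP2", "P")),
        ]}

    def test_bind_single_free_site_gives_one_product(self):
        pkar = ComplexEntity.from_simple(self.simples["PKAR"], self.simples)
        camp = ComplexEntity.from_simple(self.simples["cAMP"], self.simples)
        out = apply_reactor(Reactor("bind", "cAMP", "B"), pkar, self.sites,
                            partner=camp)
        assert len(out) == 1
        product = out[0][0]
        assert product.formula() == "PKAR.cAMP"

    def test_add_blocked_when_site_occupied(self):
        phospho = complex_from(self.simples, ["AQP2", "P"],
                               [(0, 1, "s256")])
        out = apply_reactor(Reactor("add", "P", "s256"), phospho, self.sites)
        assert out == []  # condition filter: the site is already modified

    def test_release_splits_holoenzyme_with_two_camp(self):
        holo = complex_from(self.simples,
                            ["PKAR", "PKAC", "cAMP", "cAMP"],
                            [(0, 1, "rc"), (0, 2, "A"), (0, 3, "B")])
        out = apply_reactor(Reactor("release", "PKAC", "rc"), holo,
                            self.sites)
        assert len(out) == 1
        formulas = sorted(p.formula() for p in out[0])
        assert formulas == ["PKAC", "PKAR.2cAMP"]

    def test_release_on_unbonded_pair_is_no_match(self):
        pkar = ComplexEntity.from_simple(self.simples["PKAR"], self.simples)
        assert apply_reactor(Reactor("release", "PKAC", "rc"), pkar,
                             self.sites) == []

    def test_undeclared_site_is_rule_definition_error(self):
        pkar = ComplexEntity.from_simple(self.simples["PKAR"], self.simples)
        with pytest.raises(RuleDefinitionError):
            apply_reactor(Reactor("add", "P", "nope"), pkar, self.sites)

    def test_ambiguous_auto_site_is_error(self):
        # two declared sites match (PKAR, cAMP): no silent guess
        pkar = ComplexEntity.from_simple(self.simples["PKAR"], self.simples)
        camp = ComplexEntity.from_simple(self.simples["cAMP"], self.simples)
        with pytest.raises(RuleDefinitionError, match="ambiguous"):
            apply_reactor(Reactor("bind", "cAMP", None), pkar, self.sites,
                          partner=camp)

    def test_small_molecule_binds_one_partner_at_a_time(self):
        bound = complex_from(self.simples, ["PKAR", "cAMP"], [(0, 1, "A")])
        camp_node = bound.nodes_of("cAMP")[0]
        assert not bound.node_site_free(camp_node, "B")

    def test_bind_and_release_conserve_composition(self):
        pkar = ComplexEntity.from_simple(self.simples["PKAR"], self.simples)
        camp = ComplexEntity.from_simple(self.simples["cAMP"], self.simples)
        joined = apply_reactor(Reactor("bind", "cAMP", "A"), pkar,
                               self.sites, partner=camp)[0][0]
        assert joined.entity_counts() == {"PKAR": 1, "cAMP": 1}
        back = apply_reactor(Reactor("release", "cAMP", "A"), joined,
                             self.sites)
        merged = {}
        for prod in back[0]:
            for k, v in prod.entity_counts().items():
                merged[k] = merged.get(k, 0) + v
        assert merged == {"PKAR": 1, "cAMP": 1}


# ---------------------------------------------------------------------------
# Canonical form
# ---------------------------------------------------------------------------

class TestCanonicalForm:
    def test_build_order_irrelevant(self):
        simples = make_simples("A", "B")
        site = [BindingSite("ab", ("A", "B"))]
        one = complex_from(simples, ["A", "B"], [(0, 1, "ab")])
        other = complex_from(simples, ["B", "A"], [(0, 1, "ab")])
        assert one == other
        assert hash(one) == hash(other)

    def test_different_partners_differ(self):
        simples = make_simples("A", "B", "C")
        ab = complex_from(simples, ["A", "B"], [(0, 1, "x")])
        ac = complex_from(simples, ["A", "C"], [(0, 1, "x")])
        assert ab != ac

    def test_same_formula_different_sites_differ(self):
        simples = make_simples("R", "c", small=("c",))
        at_a = complex_from(simples, ["R", "c"], [(0, 1, "siteA")])
        at_b = complex_from(simples, ["R", "c"], [(0, 1, "siteB")])
        assert at_a.formula() == at_b.formula()
        assert at_a != at_b

    def test_random_six_node_complexes_match_brute_force_isomorphism(self):
        """Canonical-label equality agrees with an exhaustive permutation
        isomorphism check on random 6-node site-labeled trees."""
        rng = np.random.default_rng(7)
        simples = make_simples("A", "B", "C")

        def random_tree():
            nodes = [str(rng.choice(["A", "B", "C"])) for _ in range(6)]
            edges = []
            for k in range(1, 6):
                parent = int(rng.integers(0, k))
                site = f"s{int(rng.integers(0, 2))}"
                edges.append((parent, k, site))
            return complex_from(simples, nodes, edges)

        def brute_force_isomorphic(x, y):
            gx, gy = x.graph, y.graph
            nx_nodes, ny_nodes = list(gx.nodes), list(gy.nodes)
            for perm in itertools.permutations(ny_nodes):
                mapping = dict(zip(nx_nodes, perm))
                if any(gx.nodes[n]["entity"] != gy.nodes[mapping[n]]["entity"]
                       for n in nx_nodes):
                    continue
                ok = gx.number_of_edges() == gy.number_of_edges()
                for u, v, d in gx.edges(data=True):
                    mu, mv = mapping[u], mapping[v]
                    if not gy.has_edge(mu, mv) or \
                            gy.edges[mu, mv]["site"] != d["site"]:
                        ok = False
                        break
                if ok:
                    return True
            return False

        pairs = [(random_tree(), random_tree()) for _ in range(20)]
        # include guaranteed-isomorphic pairs (relabeled copies)
        for _ in range(5):
            t = random_tree()
            g2 = nx.relabel_nodes(t.graph, {n: 10 + n for n in t.graph})
            pairs.append((t, ComplexEntity(g2, simples)))
        for x, y in pairs:
            assert (x.canonical_label() == y.canonical_label()) == \
                brute_force_isomorphic(x, y)


# ---------------------------------------------------------------------------
# Network generation
# ---------------------------------------------------------------------------

def modification_model(k):
    simples = make_simples("X", "P", small=("P",))
    sites = [BindingSite(f"s{i}", ("X", "P")) for i in range(k)]
    rules = []
    for i in range(k):
        rules.append(ReactionRule(f"mod{i}", [Reactor("add", "P", f"s{i}")]))
        rules.append(ReactionRule(f"unmod{i}",
                                  [Reactor("remove", "P", f"s{i}")]))
    seeds = [ComplexEntity.from_simple(simples["X"], simples)]
    return rules, seeds, sites


class TestNetworkGeneration:
    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    def test_k_independent_sites_give_2_to_k_states(self, k):
        rules, seeds, sites = modification_model(k)
        net = generate_network(rules, seeds, sites)
        assert len(net.entities) == 2 ** k

    def test_empty_rule_set_is_identity(self):
        simples = make_simples("A", "B")
        seeds = [ComplexEntity.from_simple(simples[n], simples)
                 for n in ("A", "B")]
        net = generate_network([], seeds, [])
        assert len(net.entities) == 2
        assert net.reactions == []

    def test_generation_is_idempotent(self):
        rules, seeds, sites = modification_model(3)
        net = generate_network(rules, seeds, sites)
        again = generate_network(rules, list(net.entities.values()), sites)
        assert set(again.entities) == set(net.entities)
        assert set(again.reactions) == set(net.reactions)

    def test_unbounded_polymerization_raises_divergence(self):
        # head/tail sites let chains extend indefinitely
        simples = make_simples("M")
        sites = [BindingSite("head", ("M", "M")),
                 BindingSite("tail", ("M", "M"))]
        rules = [
            ReactionRule("grow_head", [Reactor("bind", "M", "head")]),
            ReactionRule("grow_tail", [Reactor("bind", "M", "tail")]),
        ]
        seeds = [ComplexEntity.from_simple(simples["M"], simples)]
        with pytest.raises(NetworkGenerationError):
            generate_network(rules, seeds, sites, max_complex_size=8)

    def test_single_site_polymerization_saturates_at_dimer(self):
        # one declared site per node pair: a second bond at the same site
        # is blocked, so the network closes at the dimer
        simples = make_simples("M")
        sites = [BindingSite("mm", ("M", "M"))]
        rules = [ReactionRule("dimerize", [Reactor("bind", "M", "mm")])]
        seeds = [ComplexEntity.from_simple(simples["M"], simples)]
        net = generate_network(rules, seeds, sites)
        assert {ce.formula() for ce in net.entities.values()} == {"M", "2M"}

    def test_tracks_start_at_substrates_and_end_at_products(self):
        rules, seeds, sites = modification_model(2)
        net = generate_network(rules, seeds, sites)
        for rx, track in net.tracks.items():
            for s in rx.substrates:
                assert s in track
            for p in rx.products:
                assert p in track

    def test_signalosome_network_closes(self, signalosome):
        """The PKA/AQP2 rule set reaches a fixpoint with every expected
        molecular species class present."""
        formulas = {ce.formula() for ce in signalosome.entities.values()}
        assert "PKAC" in formulas                      # free catalytic subunit
        assert "AKAP.PKAC.PKAR.2cAMP" in formulas      # loaded holoenzyme
        assert "AQP2.P" in formulas                    # phospho-AQP2
        assert "AMP" in formulas                       # hydrolysis product
        # closed under the rules: regeneration adds nothing
        assert len(signalosome.reactions) > 50


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=1, max_value=4))
def test_entity_count_property(k):
    rules, seeds, sites = modification_model(k)
    assert len(generate_network(rules, seeds, sites).entities) == 2 ** k
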