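"""Chemical entities as graphs and rule-based reaction-network generation.

The unit of all chemistry here is the *complex entity*: a connected graph
whose nodes are occurrences of simple chemical entities (proteins, small
molecules, phosphate groups) and whose edges are bonds formed at declared
binding sites.  There are no states on entities: a phosphorylation is the
addition of a phosphate node, a cAMP-loaded receptor is a receptor node
bonded to a cAMP node.  Reaction rules are chains of four elementary
reactors (ADD, BIND, REMOVE, RELEASE) plus predicates restricting the
candidate reactants; iterating rule application over a growing pool of
entities to a fixpoint yields the full reaction network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "SimpleEntity",
    "BindingSite",
    "ComplexEntity",
    "Reactor",
    "Condition",
    "ReactionRule",
    "Reaction",
    "ReactionNetwork",
    "RuleDefinitionError",
    "NetworkGenerationError",
    "generate_network",
]


class RuleDefinitionError(ValueError):
    """A rule references undeclared entities/sites or is structurally invalid."""


class NetworkGenerationError(RuntimeError):
    """Network generation failed to reach a fixpoint (unbounded growth)."""


@dataclass(frozen=True)
class SimpleEntity:
    """A simple chemical entity (SE): the indivisible node of all complexes.

    Small molecules (cAMP, ATP, phosphate) carry a single binding site and
    participate in at most one bond at a time.  Membrane-bound entities
    taint every complex that contains them as membrane-bound unless the
    complex overrides the flag.
    """

    name: str
    small_molecule: bool = False
    membrane_bound: bool = False


@dataclass(frozen=True)
class BindingSite:
    """A named binding site: an ordered pair of simple-entity names.

    An edge between nodes of entities (v1, v2) may only exist if a site
    declaring that pair exists; the edge is labeled with the site name.
    """

    name: str
    pair: tuple[str, str]

    def matches(self, a: str, b: str) -> bool:
        return (self.pair == (a, b)) or (self.pair == (b, a))


class ComplexEntity:
    """A connected graph of simple-entity occurrences bonded at named sites.

    Identity is structural: two complexes compare equal iff their graphs are
    isomorphic respecting node entity names and edge site labels.  The
    canonical label realizing this is computed by color refinement followed
    by exhaustive minimization within refined color classes, which is exact
    for any size and cheap for the nearly-asymmetric graphs chemistry
    produces.
    """

    def __init__(self, graph: nx.Graph, simples: dict[str, SimpleEntity],
                 membrane_override: bool | None = None):
        if graph.number_of_nodes() == 0:
            raise ValueError("complex entity must contain at least one node")
        if not nx.is_connected(graph):
            raise ValueError("complex entity graph must be connected")
        self.graph = graph
        self.simples = simples
        self.membrane_override = membrane_override
        self._label: str | None = None

    # -- construction -----------------------------------------------------
    @classmethod
    def from_simple(cls, se: SimpleEntity,
                    simples: dict[str, SimpleEntity]) -> "ComplexEntity":
        g = nx.Graph()
        g.add_node(0, entity=se.name)
        return cls(g, simples)

    def copy(self) -> "ComplexEntity":
        return ComplexEntity(self.graph.copy(), self.simples,
                             self.membrane_override)

    # -- basic queries ----------------------------------------------------
    @property
    def size(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def membrane_bound(self) -> bool:
        if self.membrane_override is not None:
            return self.membrane_override
        return any(self.simples[d["entity"]].membrane_bound
                   for _, d in self.graph.nodes(data=True))

    def entity_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            counts[d["entity"]] = counts.get(d["entity"], 0) + 1
        return counts

    def has_part(self, name: str) -> bool:
        return any(d["entity"] == name for _, d in self.graph.nodes(data=True))

    def count_part(self, name: str) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True)
                   if d["entity"] == name)

    def nodes_of(self, name: str) -> list[int]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["entity"] == name]

    def site_edges(self, site: str) -> list[tuple[int, int]]:
        return [(u, v) for u, v, d in self.graph.edges(data=True)
                if d["site"] == site]

    def node_site_free(self, node: int, site: str) -> bool:
        """True if `node` carries no bond labeled `site` and, for small
        molecules, no bond at all."""
        ent = self.simples[self.graph.nodes[node]["entity"]]
        if ent.small_molecule and self.graph.degree(node) > 0:
            return False
        return all(self.graph.edges[node, nb]["site"] != site
                   for nb in self.graph.neighbors(node))

    def free_nodes_at(self, entity: str, site: str) -> list[int]:
        return [n for n in self.nodes_of(entity)
                if self.node_site_free(n, site)]

    # -- canonical form ----------------------------------------------------
    def canonical_label(self) -> str:
        if self._label is None:
            self._label = _canonical_label(self.graph)
        return self._label

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexEntity):
            return NotImplemented
        return self.canonical_label() == other.canonical_label()

    def __hash__(self) -> int:
        return hash(self.canonical_label())

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"ComplexEntity({self.canonical_label()})"

    # human-readable composition, e.g. "PKAR.2cAMP.PKAC"
    def formula(self) -> str:
        counts = self.entity_counts()
        parts = []
        for name in sorted(counts):
            n = counts[name]
            parts.append(f"{n}{name}" if n > 1 else name)
        return ".".join(parts)


def _refine_colors(g: nx.Graph) -> dict[int, int]:
    """Iterative color refinement on (entity, incident site multiset)."""
    color = {n: (g.nodes[n]["entity"],) for n in g.nodes}
    while True:
        sig = {}
        for n in g.nodes:
            nbs = sorted((g.edges[n, m]["site"], color[m]) for m in g.neighbors(n))
            sig[n] = (color[n], tuple(nbs))
        # compress signatures to ints, stable by sorted signature
        classes = sorted(set(sig.values()))
        new_color = {n: classes.index(sig[n]) for n in g.nodes}
        if len(set(new_color.values())) == len(set(color.values())):
            return new_color
        color = {n: (new_color[n],) for n in g.nodes}


def _canonical_label(g: nx.Graph) -> str:
    """Exact canonical label: minimal adjacency encoding over all node
    orderings compatible with the refined coloring.

    Within each refined color class every permutation is tried, so two
    graphs receive equal labels iff they are isomorphic (respecting node
    entity names and edge site labels).  Color classes are almost always
    singletons here, keeping this effectively linear.
    """
    color = _refine_colors(g)
    classes: dict[int, list[int]] = {}
    for n, c in color.items():
        classes.setdefault(c, []).append(n)
    ordered_classes = [sorted(classes[c]) for c in sorted(classes)]

    best: str | None = None
    for perm_parts in itertools.product(
            *(itertools.permutations(cls) for cls in ordered_classes)):
        order = [n for part in perm_parts for n in part]
        index = {n: i for i, n in enumerate(order)}
        nodes_enc = ",".join(g.nodes[n]["entity"] for n in order)
        edges = sorted(
            (min(index[u], index[v]), max(index[u], index[v]), d["site"])
            for u, v, d in g.edges(data=True))
        edges_enc = ";".join(f"{i}-{j}:{s}" for i, j, s in edges)
        enc = nodes_enc + "|" + edges_enc
        if best is None or enc < best:
            best = enc
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Reactors and conditions
# ---------------------------------------------------------------------------

_REACTOR_KINDS = ("add", "bind", "remove", "release")


@dataclass(frozen=True)
class Reactor:
    """One elementary transformation in a reaction chain.

    kind:    'add'     attach a fresh component B to the current entity A
             'bind'    join two available reactants A and B
             'remove'  delete component B from A-B (B vanishes)
             'release' split A-B into products A and B (terminates the chain)
    entity:  name of the component B being added/bound/removed/released
    site:    binding-site name; None requests automatic assignment, which
             succeeds only if exactly one declared site matches the pair.
    """

    kind: str
    entity: str
    site: str | None = None

    def __post_init__(self):
        if self.kind not in _REACTOR_KINDS:
            raise RuleDefinitionError(f"unknown reactor kind {self.kind!r}")


@dataclass(frozen=True)
class Condition:
    """Predicate restricting candidate reactants of a rule.

    Closed predicate set: has_part, lacks_part, site_free, site_occupied,
    count_of_part.  `target` selects which reactant the predicate applies
    to: 'primary' (the entity the chain transforms) or 'partner' (the
    second reactant of a leading BIND).
    """

    kind: str
    value: str
    count: int | None = None
    target: str = "primary"

    def check(self, ce: ComplexEntity) -> bool:
        if self.kind == "has_part":
            return ce.has_part(self.value)
        if self.kind == "lacks_part":
            return not ce.has_part(self.value)
        if self.kind == "site_free":
            return len(ce.site_edges(self.value)) == 0
        if self.kind == "site_occupied":
            return len(ce.site_edges(self.value)) > 0
        if self.kind == "count_of_part":
            return ce.count_part(self.value) == self.count
        raise RuleDefinitionError(f"unknown condition kind {self.kind!r}")


@dataclass
class ReactionRule:
    """A chain of reactors with conditions and rate parameters.

    Every reaction the rule generates inherits `rate_constants`; a leading
    BIND produces second-order reactions, anything else first-order.
    RELEASE, if present, must terminate the chain.
    """

    name: str
    chain: Sequence[Reactor]
    conditions: Sequence[Condition] = ()
    rate_constants: dict = field(default_factory=lambda: {"k": 1.0})
    rate_law: str = "mass_action"

    def __post_init__(self):
        if len(self.chain) < 1:
            raise RuleDefinitionError(f"rule {self.name}: empty chain")
        for i, r in enumerate(self.chain):
            if r.kind == "release" and i != len(self.chain) - 1:
                raise RuleDefinitionError(
                    f"rule {self.name}: RELEASE must terminate the chain")


@dataclass(frozen=True)
class Reaction:
    """An elementary generated reaction (substrate/product canonical labels)."""

    substrates: tuple[str, ...]
    products: tuple[str, ...]
    rate_law: str
    rate_constants: tuple[tuple[str, float], ...]
    rule: str

    @property
    def order(self) -> int:
        return len(self.substrates)


@dataclass
class ReactionNetwork:
    """Closure of the rules over the seed entities.

    entities maps canonical label -> ComplexEntity; reactions is the
    deduplicated list of elementary reactions; tracks maps each reaction to
    its substrate -> intermediate -> product lineage (canonical labels).
    """

    entities: dict[str, ComplexEntity]
    reactions: list[Reaction]
    tracks: dict[Reaction, tuple[str, ...]]

    def formula(self, label: str) -> str:
        return self.entities[label].formula()

    def to_table(self):
        """Flat reaction list as a pandas DataFrame (for CSV export)."""
        import pandas as pd
        rows = []
        for rx in self.reactions:
            rows.append({
                "substrates": " + ".join(self.formula(s) for s in rx.substrates),
                "products": " + ".join(self.formula(p) for p in rx.products),
                "law": rx.rate_law,
                "constants": ";".join(f"{k}={v}" for k, v in rx.rate_constants),
                "rule": rx.rule,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Reactor application
# ---------------------------------------------------------------------------

def _resolve_site(sites: dict[str, BindingSite], reactor: Reactor,
                  primary_entities: Iterable[str]) -> BindingSite:
    """Find the declared site for a reactor; auto-assign only if unique."""
    if reactor.site is not None:
        site = sites.get(reactor.site)
        if site is None:
            raise RuleDefinitionError(f"no declared binding site {reactor.site!r}")
        return site
    matching = [s for s in sites.values()
                if reactor.entity in s.pair]
    matching = [s for s in matching
                if any(s.matches(reactor.entity, p) for p in primary_entities)]
    if len(matching) == 1:
        return matching[0]
    if not matching:
        raise RuleDefinitionError(
            f"no declared binding site for pair involving {reactor.entity!r}")
    raise RuleDefinitionError(
        f"ambiguous automatic site assignment for {reactor.entity!r}: "
        + ", ".join(s.name for s in matching))


def _attach(ce: ComplexEntity, node: int, new_entity: str,
            site: str) -> ComplexEntity:
    g = ce.graph.copy()
    new_node = max(g.nodes) + 1
    g.add_node(new_node, entity=new_entity)
    g.add_edge(node, new_node, site=site)
    return ComplexEntity(g, ce.simples, ce.membrane_override)


def _join(a: ComplexEntity, na: int, b: ComplexEntity, nb: int,
          site: str) -> ComplexEntity:
    g = a.graph.copy()
    offset = max(g.nodes) + 1
    mapping = {n: n + offset for n in b.graph.nodes}
    for n, d in b.graph.nodes(data=True):
        g.add_node(mapping[n], **d)
    for u, v, d in b.graph.edges(data=True):
        g.add_edge(mapping[u], mapping[v], **d)
    g.add_edge(na, mapping[nb], site=site)
    return ComplexEntity(g, a.simples)


def _split(ce: ComplexEntity, u: int, v: int) -> tuple[ComplexEntity, ComplexEntity]:
    """Cut edge (u, v); return (component containing u, component containing v)."""
    g = ce.graph.copy()
    g.remove_edge(u, v)
    comp_u = nx.node_connected_component(g, u)
    comp_v = nx.node_connected_component(g, v)
    gu = g.subgraph(comp_u).copy()
    gv = g.subgraph(comp_v).copy()
    return (ComplexEntity(gu, ce.simples), ComplexEntity(gv, ce.simples))


def apply_reactor(reactor: Reactor, primary: ComplexEntity,
                  sites: dict[str, BindingSite],
                  partner: ComplexEntity | None = None
                  ) -> list[tuple[ComplexEntity, ...]]:
    """Apply one reactor to a candidate; return all distinct outcomes.

    Each outcome is a tuple of product entities (two entries only for
    RELEASE).  An empty list is a no-match, never an error; undeclared
    sites raise RuleDefinitionError.
    """
    prim_entities = set(primary.entity_counts())
    if reactor.kind == "bind" and partner is not None:
        prim_entities |= set(partner.entity_counts())
    site = _resolve_site(sites, reactor, prim_entities)
    other = site.pair[0] if site.pair[1] == reactor.entity else site.pair[1]

    outcomes: list[tuple[ComplexEntity, ...]] = []
    seen: set[tuple[str, ...]] = set()

    def emit(*prods: ComplexEntity):
        key = tuple(sorted(p.canonical_label() for p in prods))
        if key not in seen:
            seen.add(key)
            outcomes.append(prods)

    if reactor.kind == "add":
        for n in primary.free_nodes_at(other, site.name):
            emit(_attach(primary, n, reactor.entity, site.name))
    elif reactor.kind == "bind":
        if partner is None:
            raise RuleDefinitionError("BIND requires a second reactant")
        # primary must expose a free node of `other`, partner of reactor.entity
        for na in primary.free_nodes_at(other, site.name):
            for nb in partner.free_nodes_at(reactor.entity, site.name):
                emit(_join(primary, na, partner, nb, site.name))
    elif reactor.kind in ("remove", "release"):
        for u, v in primary.site_edges(site.name):
            # orient the edge: v_keep is the side NOT being removed/released
            eu = primary.graph.nodes[u]["entity"]
            ev = primary.graph.nodes[v]["entity"]
            if ev == reactor.entity:
                keep, drop = u, v
            elif eu == reactor.entity:
                keep, drop = v, u
            else:
                continue
            kept, dropped = _split(primary, keep, drop)
            if reactor.kind == "remove":
                # only the single removed component vanishes; a REMOVE that
                # would strand a multi-node fragment is not a match
                if dropped.size == 1:
                    emit(kept)
            else:
                emit(kept, dropped)
    return outcomes


def _apply_rule(rule: ReactionRule, pool: dict[str, ComplexEntity],
                sites: dict[str, BindingSite]
                ) -> list[tuple[Reaction, tuple[str, ...], list[ComplexEntity]]]:
    """Enumerate every application of a rule chain over the pool.

    Returns (reaction, track, products) triples; the track records
    canonical labels of substrate(s), each intermediate, and the products.
    """
    results: list[tuple[Reaction, tuple[str, ...], list[ComplexEntity]]] = []
    head = rule.chain[0]
    prim_conds = [c for c in rule.conditions if c.target == "primary"]
    part_conds = [c for c in rule.conditions if c.target == "partner"]

    if head.kind == "bind":
        candidates = [
            (a, b) for a in pool.values() for b in pool.values()
            if all(c.check(a) for c in prim_conds)
            and all(c.check(b) for c in part_conds)
        ]
        starts = [((a, b), apply_reactor(head, a, sites, partner=b))
                  for a, b in candidates]
    else:
        candidates = [a for a in pool.values()
                      if all(c.check(a) for c in prim_conds)]
        starts = [((a,), apply_reactor(head, a, sites)) for a in candidates]

    for substrates, first_products in starts:
        sub_labels = tuple(s.canonical_label() for s in substrates)
        for prods in first_products:
            # walk the rest of the chain on the working intermediate (the
            # first product); chains branch if a reactor matches multiple
            # distinct positions, generating one reaction per branch
            pending = [(list(prods), [*sub_labels])]
            for reactor in rule.chain[1:]:
                nxt_pending = []
                for current, track in pending:
                    work = current[0]
                    for branch in apply_reactor(reactor, work, sites):
                        nxt_pending.append((
                            [*branch, *current[1:]],
                            [*track, work.canonical_label()],
                        ))
                pending = nxt_pending
            for final, track in pending:
                prod_labels = tuple(sorted(p.canonical_label() for p in final))
                rx = Reaction(
                    substrates=tuple(sorted(sub_labels)),
                    products=prod_labels,
                    rate_law=rule.rate_law,
                    rate_constants=tuple(sorted(rule.rate_constants.items())),
                    rule=rule.name,
                )
                if rx.substrates == rx.products:
                    continue  # identity transformation: not a reaction
                results.append((rx, tuple([*track, *prod_labels]), list(final)))
    return results


def generate_network(rules: Sequence[ReactionRule],
                     seed_entities: Sequence[ComplexEntity],
                     sites: Sequence[BindingSite],
                     max_complex_size: int = 16,
                     max_iterations: int = 50) -> ReactionNetwork:
    """Iterate rule application to a fixpoint over the entity pool.

    Products of each pass join the candidate pool for the next; entities
    deduplicate by canonical label and reactions by (substrates, products,
    law, constants).  Growth past `max_complex_size` nodes or failure to
    reach a fixpoint within `max_iterations` passes raises
    NetworkGenerationError naming the offending rule.
    """
    site_map = {s.name: s for s in sites}
    pool: dict[str, ComplexEntity] = {
        e.canonical_label(): e for e in seed_entities}
    if pool and max(e.size for e in pool.values()) > max_complex_size:
        raise ValueError("max_complex_size smaller than largest seed complex")

    reactions: dict[Reaction, tuple[str, ...]] = {}
    for _ in range(max_iterations):
        new_entities: dict[str, ComplexEntity] = {}
        for rule in rules:
            for rx, track, prods in _apply_rule(rule, pool, site_map):
                if rx not in reactions:
                    reactions[rx] = track
                for ent in prods:
                    label = ent.canonical_label()
                    if label not in pool and label not in new_entities:
                        if ent.size > max_complex_size:
                            raise NetworkGenerationError(
                                f"rule {rule.name!r} grows complexes past "
                                f"max_complex_size={max_complex_size}")
                        new_entities[label] = ent
        if not new_entities:
            return ReactionNetwork(pool, list(reactions), dict(reactions))
        pool.update(new_entities)
    raise NetworkGenerationError(
        "no fixpoint within iteration cap; offending rule(s): "
        + ", ".join(sorted({rx.rule for rx in reactions})))
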