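"""Runnable PKA/AQP2 model configurations and their observables.

Four models of increasing scope, all built on the same rule-generated
signalosome chemistry:

* phosphorylation model -- well-mixed PKA activation: PKAR (anchored to
  AKAP) binds two cAMP at sites A and B and only then releases PKAC;
  released PKAC phosphorylates PKAR (reducing PKAC rebinding, a positive
  feedback), AQP2 at S256, PDE4 at S54 (raising its cAMP hydrolysis, a
  negative feedback), and -- in the endocytosis-coupled variants -- CSK,
  which phosphorylates and thereby inhibits SRC.  PP2B reverses the
  phosphorylations.
* compartmentalization model -- cAMP diffusion on a grid with a
  diffusion-restricted vesicle-storage region (optionally ringed by a
  membrane with passages) holding the PDE4 sink.
* endocytosis model -- a 1 um^2 apical membrane patch with AQP2 cargo,
  stochastic pit formation, and SRC-regulated cargo collection.
* full recycling model -- storage region with AQP2 vesicles, actin
  transport to the apical membrane, SNARE fusion, endocytosis and
  microtubule return, under the printed stepped cAMP influx schedule.

Kinetic constants not printed in the main text are physiological
placeholders (flagged in the shipped configs); the basal kinase /
phosphatase balance is calibrated so the resting AQP2-S256
phospho-ratio sits at the documented basal value of 0.46.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from mesocell.entities import (BindingSite, ComplexEntity, Condition,
                               ReactionRule, Reactor, SimpleEntity,
                               generate_network, ReactionNetwork)
from mesocell.integrator import (ControllerConfig, ErrorController,
                                 Simulation)
from mesocell.kinetics import (CompartmentExchange, Diffusion, Influx,
                               MassActionReaction, MembraneDiffusion1D,
                               MichaelisMentenReaction, Module,
                               ReactionGroup)
from mesocell.space import Region, SimulationSpace
from mesocell.state import StateLayout

__all__ = [
    "PhosphoParams",
    "build_signalosome",
    "species_name",
    "network_modules",
    "PhosphoResult",
    "run_phospho_model",
    "CompartmentParams",
    "CompartmentResult",
    "make_storage_space",
    "run_compartment_model",
    "EndocytosisModelParams",
    "EndocytosisResult",
    "run_endocytosis_model",
    "FullModelParams",
    "FullModelResult",
    "run_full_model",
    "full_influx_schedule",
]


# ---------------------------------------------------------------------------
# Signalosome network
# ---------------------------------------------------------------------------

@dataclass
class PhosphoParams:
    """Rate constants and pools of the phosphorylation model.

    Units: uM, s.  Influx in uM/s (the printed values are nM/s: 50 basal,
    200 stimulating -> 0.05 / 0.2 uM/s).  cAMP-PKAR binding defaults to
    the printed 0.07 uM^-1 s^-1.  Everything else is a physiological
    placeholder calibrated once against the documented basal S256
    phospho-ratio of 0.46.
    """

    # cAMP binding at the two PKAR sites (KD ~ 0.3 uM)
    k_camp_on_a: float = 0.07
    k_camp_off_a: float = 0.02
    k_camp_on_b: float = 0.07
    k_camp_off_b: float = 0.02
    # PKAC release / rebinding (phospho-PKAR binds PKAC weakly)
    k_pkac_release: float = 2.0
    k_pkac_bind: float = 2.0
    k_pkac_bind_phospho: float = 0.05
    # PKAC autophosphorylation of bound PKAR
    k_pkar_phos: float = 0.3
    # kinase-substrate binding / catalysis / unproductive unbinding
    k_sub_bind: float = 1.0
    k_sub_unbind: float = 1.0
    k_cat_aqp2: float = 3.0
    k_cat_pde4: float = 3.0
    # PP2B phosphatase (binding calibrated to the 0.46 basal ratio)
    k_pp2b_bind: float = 0.048
    k_pp2b_unbind: float = 1.0
    k_dephos: float = 2.0
    # PDE4 hydrolysis (elementary: bind cAMP, convert to AMP)
    k_pde_camp_on: float = 2.0
    k_pde_camp_off: float = 1.0
    k_hydrolysis: float = 1.0
    k_hydrolysis_phospho: float = 3.0
    # CSK / SRC arm (endocytosis-coupled variants)
    k_csk_bind: float = 1.0
    k_cat_csk: float = 2.0
    k_src_bind: float = 1.0
    k_cat_src: float = 2.0
    k_csk_dephos: float = 0.05
    k_src_dephos: float = 0.05
    # pools (uM)
    pkar_total: float = 2.0
    pkac_total: float = 1.0
    pde4_total: float = 0.2
    pp2b_total: float = 0.5
    aqp2_total: float = 2.0
    csk_total: float = 0.5
    src_total: float = 0.5
    # influx (uM/s)
    camp_influx: float = 0.05
    max_complex_size: int = 16


def _simples(include_src: bool) -> dict[str, SimpleEntity]:
    names = {
        "AKAP": SimpleEntity("AKAP"),
        "PKAR": SimpleEntity("PKAR"),
        "PKAC": SimpleEntity("PKAC"),
        "PP2B": SimpleEntity("PP2B"),
        "PDE4": SimpleEntity("PDE4"),
        "AQP2": SimpleEntity("AQP2", membrane_bound=True),
        "cAMP": SimpleEntity("cAMP", small_molecule=True),
        "AMP": SimpleEntity("AMP", small_molecule=True),
        "P": SimpleEntity("P", small_molecule=True),
    }
    if include_src:
        names["CSK"] = SimpleEntity("CSK")
        names["SRC"] = SimpleEntity("SRC")
    return names


def _sites(include_src: bool) -> list[BindingSite]:
    sites = [
        BindingSite("anchor", ("AKAP", "PKAR")),
        BindingSite("siteA", ("PKAR", "cAMP")),
        BindingSite("siteB", ("PKAR", "cAMP")),
        BindingSite("rc", ("PKAR", "PKAC")),
        BindingSite("rp", ("PKAR", "P")),
        BindingSite("s256", ("AQP2", "P")),
        BindingSite("s54", ("PDE4", "P")),
        BindingSite("ca", ("PKAC", "AQP2")),
        BindingSite("cd", ("PKAC", "PDE4")),
        BindingSite("pa", ("PP2B", "AQP2")),
        BindingSite("pr", ("PP2B", "PKAR")),
        BindingSite("pd", ("PP2B", "PDE4")),
        BindingSite("dcamp", ("PDE4", "cAMP")),
        BindingSite("damp", ("PDE4", "AMP")),
    ]
    if include_src:
        sites += [
            BindingSite("s364", ("CSK", "P")),
            BindingSite("y527", ("SRC", "P")),
            BindingSite("cc", ("PKAC", "CSK")),
            BindingSite("cs", ("CSK", "SRC")),
        ]
    return sites


def _rules(p: PhosphoParams, include_src: bool) -> list[ReactionRule]:
    R, C = Reactor, Condition
    rules = [
        # cAMP loading of PKAR (sites A and B, both required for release)
        ReactionRule("camp_bind_A", [R("bind", "cAMP", "siteA")],
                     [C("has_part", "PKAR")],
                     {"k": p.k_camp_on_a}),
        ReactionRule("camp_unbind_A", [R("release", "cAMP", "siteA")],
                     rate_constants={"k": p.k_camp_off_a}),
        ReactionRule("camp_bind_B", [R("bind", "cAMP", "siteB")],
                     [C("has_part", "PKAR")],
                     {"k": p.k_camp_on_b}),
        ReactionRule("camp_unbind_B", [R("release", "cAMP", "siteB")],
                     rate_constants={"k": p.k_camp_off_b}),
        # PKAC release only with both cAMP sites occupied
        ReactionRule("pkac_release", [R("release", "PKAC", "rc")],
                     [C("site_occupied", "siteA"), C("site_occupied", "siteB")],
                     {"k": p.k_pkac_release}),
        # PKAC rebinding; phospho-PKAR binds weakly (positive feedback)
        ReactionRule("pkac_bind", [R("bind", "PKAC", "rc")],
                     [C("site_free", "rp"), C("has_part", "PKAR"),
                      C("lacks_part", "AKAP", target="partner"),
                      C("lacks_part", "AQP2", target="partner"),
                      C("lacks_part", "PDE4", target="partner"),
                      C("lacks_part", "CSK", target="partner")],
                     {"k": p.k_pkac_bind}),
        ReactionRule("pkac_bind_phospho", [R("bind", "PKAC", "rc")],
                     [C("site_occupied", "rp"), C("has_part", "PKAR"),
                      C("lacks_part", "AKAP", target="partner"),
                      C("lacks_part", "AQP2", target="partner"),
                      C("lacks_part", "PDE4", target="partner"),
                      C("lacks_part", "CSK", target="partner")],
                     {"k": p.k_pkac_bind_phospho}),
        # bound PKAC phosphorylates its own PKAR (stays trapped)
        ReactionRule("pkar_phos", [R("add", "P", "rp")],
                     [C("site_occupied", "rc")],
                     {"k": p.k_pkar_phos}),
        # AQP2: bind free PKAC, phosphorylate+release, or unbind
        ReactionRule("aqp2_bind",
                     [R("bind", "AQP2", "ca")],
                     [C("lacks_part", "PKAR"), C("lacks_part", "AQP2"),
                      C("lacks_part", "PDE4"), C("lacks_part", "CSK"),
                      C("site_free", "s256", target="partner"),
                      C("lacks_part", "PP2B", target="partner")],
                     {"k": p.k_sub_bind}),
        ReactionRule("aqp2_phos",
                     [R("add", "P", "s256"), R("release", "PKAC", "ca")],
                     rate_constants={"k": p.k_cat_aqp2}),
        ReactionRule("aqp2_unbind", [R("release", "PKAC", "ca")],
                     rate_constants={"k": p.k_sub_unbind}),
        # PDE4: same motif; phospho-PDE4 hydrolyzes faster
        ReactionRule("pde4_bind",
                     [R("bind", "PDE4", "cd")],
                     [C("lacks_part", "PKAR"), C("lacks_part", "AQP2"),
                      C("lacks_part", "PDE4"), C("lacks_part", "CSK"),
                      C("site_free", "s54", target="partner"),
                      C("lacks_part", "PP2B", target="partner"),
                      C("lacks_part", "cAMP", target="partner")],
                     {"k": p.k_sub_bind}),
        ReactionRule("pde4_phos",
                     [R("add", "P", "s54"), R("release", "PKAC", "cd")],
                     rate_constants={"k": p.k_cat_pde4}),
        ReactionRule("pde4_unbind", [R("release", "PKAC", "cd")],
                     rate_constants={"k": p.k_sub_unbind}),
        # PP2B reversal of AQP2-S256
        ReactionRule("pp2b_bind_aqp2",
                     [R("bind", "AQP2", "pa")],
                     [C("lacks_part", "AQP2"), C("lacks_part", "PKAR"),
                      C("lacks_part", "PDE4"), C("lacks_part", "SRC"),
                      C("site_occupied", "s256", target="partner"),
                      C("lacks_part", "PKAC", target="partner")],
                     {"k": p.k_pp2b_bind}),
        ReactionRule("aqp2_dephos",
                     [R("remove", "P", "s256"), R("release", "PP2B", "pa")],
                     rate_constants={"k": p.k_dephos}),
        # PP2B reversal of PKAR-rp (acts on the anchored complex)
        ReactionRule("pp2b_bind_pkar",
                     [R("bind", "PKAR", "pr")],
                     [C("lacks_part", "AQP2"), C("lacks_part", "PKAR"),
                      C("lacks_part", "PDE4"), C("lacks_part", "SRC"),
                      C("site_occupied", "rp", target="partner"),
                      C("site_free", "pr", target="partner")],
                     {"k": p.k_pp2b_bind}),
        ReactionRule("pkar_dephos",
                     [R("remove", "P", "rp"), R("release", "PP2B", "pr")],
                     rate_constants={"k": p.k_dephos}),
        # PP2B reversal of PDE4-S54 (terminates the negative feedback)
        ReactionRule("pp2b_bind_pde4",
                     [R("bind", "PDE4", "pd")],
                     [C("lacks_part", "AQP2"), C("lacks_part", "PKAR"),
                      C("lacks_part", "PDE4"), C("lacks_part", "SRC"),
                      C("site_occupied", "s54", target="partner"),
                      C("lacks_part", "PKAC", target="partner"),
                      C("lacks_part", "cAMP", target="partner")],
                     {"k": p.k_pp2b_bind}),
        ReactionRule("pde4_dephos",
                     [R("remove", "P", "s54"), R("release", "PP2B", "pd")],
                     rate_constants={"k": p.k_dephos}),
        # unproductive phosphatase dissociation
        ReactionRule("pp2b_unbind_aqp2", [R("release", "PP2B", "pa")],
                     rate_constants={"k": p.k_pp2b_unbind}),
        ReactionRule("pp2b_unbind_pkar", [R("release", "PP2B", "pr")],
                     rate_constants={"k": p.k_pp2b_unbind}),
        ReactionRule("pp2b_unbind_pde4", [R("release", "PP2B", "pd")],
                     rate_constants={"k": p.k_pp2b_unbind}),
        # PDE4 hydrolysis of cAMP: bind, then convert to AMP and release
        ReactionRule("pde_camp_bind",
                     [R("bind", "cAMP", "dcamp")],
                     [C("has_part", "PDE4"), C("lacks_part", "PKAC")],
                     {"k": p.k_pde_camp_on}),
        ReactionRule("pde_camp_unbind", [R("release", "cAMP", "dcamp")],
                     rate_constants={"k": p.k_pde_camp_off}),
        ReactionRule("hydrolysis",
                     [R("remove", "cAMP", "dcamp"), R("add", "AMP", "damp"),
                      R("release", "AMP", "damp")],
                     [C("site_occupied", "dcamp"), C("site_free", "s54")],
                     {"k": p.k_hydrolysis}),
        ReactionRule("hydrolysis_phospho",
                     [R("remove", "cAMP", "dcamp"), R("add", "AMP", "damp"),
                      R("release", "AMP", "damp")],
                     [C("site_occupied", "dcamp"), C("site_occupied", "s54")],
                     {"k": p.k_hydrolysis_phospho}),
    ]
    if include_src:
        rules += [
            # PKA -> CSK(S364) -> SRC(Y527) inhibition cascade
            ReactionRule("csk_bind",
                         [R("bind", "CSK", "cc")],
                         [C("lacks_part", "PKAR"), C("lacks_part", "AQP2"),
                          C("lacks_part", "PDE4"), C("lacks_part", "CSK"),
                          C("site_free", "s364", target="partner"),
                          C("lacks_part", "SRC", target="partner")],
                         {"k": p.k_csk_bind}),
            ReactionRule("csk_phos",
                         [R("add", "P", "s364"), R("release", "PKAC", "cc")],
                         rate_constants={"k": p.k_cat_csk}),
            ReactionRule("csk_unbind", [R("release", "PKAC", "cc")],
                         rate_constants={"k": p.k_sub_unbind}),
            ReactionRule("src_bind",
                         [R("bind", "SRC", "cs")],
                         [C("has_part", "CSK"), C("lacks_part", "PKAC"),
                          C("lacks_part", "SRC"),
                          C("site_occupied", "s364"),
                          C("site_free", "y527", target="partner")],
                         {"k": p.k_src_bind}),
            ReactionRule("src_phos",
                         [R("add", "P", "y527"), R("release", "CSK", "cs")],
                         rate_constants={"k": p.k_cat_src}),
            ReactionRule("src_unbind", [R("release", "CSK", "cs")],
                         rate_constants={"k": p.k_sub_unbind}),
            # first-order reactivation (phosphatase pools folded into rates)
            ReactionRule("csk_dephos", [R("remove", "P", "s364")],
                         [C("lacks_part", "PKAC"), C("lacks_part", "SRC")],
                         {"k": p.k_csk_dephos}),
            ReactionRule("src_dephos", [R("remove", "P", "y527")],
                         [C("lacks_part", "CSK")],
                         {"k": p.k_src_dephos}),
        ]
    return rules


def species_name(ce: ComplexEntity) -> str:
    """Readable unique species name: composition plus bonded-site list."""
    sites = sorted(d["site"] for _, _, d in ce.graph.edges(data=True))
    if not sites:
        return ce.formula()
    return ce.formula() + "[" + ",".join(sites) + "]"


def build_signalosome(p: PhosphoParams, include_src: bool = False
                      ) -> tuple[ReactionNetwork, dict[str, SimpleEntity]]:
    """Generate the full signalosome reaction network from the rules."""
    simples = _simples(include_src)
    sites = _sites(include_src)
    seeds = []
    # seed complexes: anchored holoenzyme AKAP.PKAR.PKAC, anchored free
    # PKAR, and the free pools
    import networkx as nx
    g = nx.Graph()
    g.add_node(0, entity="AKAP")
    g.add_node(1, entity="PKAR")
    g.add_edge(0, 1, site="anchor")
    apkar = ComplexEntity(g, simples)
    g2 = g.copy()
    g2.add_node(2, entity="PKAC")
    g2.add_edge(1, 2, site="rc")
    holo = ComplexEntity(g2, simples)
    seeds += [apkar, holo]
    for n in ["PKAC", "PP2B", "PDE4", "AQP2", "cAMP", "AMP"]:
        seeds.append(ComplexEntity.from_simple(simples[n], simples))
    if include_src:
        for n in ["CSK", "SRC"]:
            seeds.append(ComplexEntity.from_simple(simples[n], simples))
    net = generate_network(_rules(p, include_src), seeds, sites,
                           max_complex_size=p.max_complex_size)
    return net, simples


# ---------------------------------------------------------------------------
# Network -> modules and observables
# ---------------------------------------------------------------------------

def network_modules(net: ReactionNetwork, layout: StateLayout,
                    block_of: dict[str, str], rate_scale=1.0,
                    grouped: bool = True) -> list[Module]:
    """Concentration modules for every generated reaction.

    The controller sees one local error per reaction either way; grouped
    (default) evaluates all of them vectorized in one ReactionGroup,
    ungrouped builds one MassActionReaction module per reaction (used by
    the equivalence tests)."""
    specs = []
    for n, rx in enumerate(net.reactions):
        k = dict(rx.rate_constants)["k"]
        subs: dict[str, int] = {}
        for s in rx.substrates:
            subs[s] = subs.get(s, 0) + 1
        prods: dict[str, int] = {}
        for s in rx.products:
            prods[s] = prods.get(s, 0) + 1
        specs.append((
            f"rx{n}:{rx.rule}", k,
            [(layout.indices(block_of[s]), c) for s, c in subs.items()],
            [(layout.indices(block_of[s]), c) for s, c in prods.items()]))
    if grouped:
        return [ReactionGroup("signalosome", layout, specs,
                              rate_scale=rate_scale)]
    return [MassActionReaction(name, layout, k, subs, prods,
                               rate_scale=rate_scale)
            for name, k, subs, prods in specs]


def _containing(net: ReactionNetwork, part: str) -> list[str]:
    return [lab for lab, ce in net.entities.items() if ce.has_part(part)]


def phospho_ratio(net: ReactionNetwork, concs: dict[str, float],
                  part: str, site: str) -> float:
    """Fraction of `part` occurrences whose `site` bond is present."""
    tot = phos = 0.0
    for lab, ce in net.entities.items():
        n = ce.count_part(part)
        if n == 0:
            continue
        c = concs.get(lab, 0.0)
        tot += n * c
        if ce.site_edges(site):
            phos += len(ce.site_edges(site)) * c
    return 0.0 if tot == 0 else phos / tot


def pka_activity(net: ReactionNetwork, concs: dict[str, float]) -> float:
    """Free-PKAC fraction of total PKAC."""
    free = tot = 0.0
    for lab, ce in net.entities.items():
        n = ce.count_part("PKAC")
        if n == 0:
            continue
        c = concs.get(lab, 0.0)
        tot += n * c
        if ce.size == 1:
            free += c
    return 0.0 if tot == 0 else free / tot


@dataclass
class PhosphoResult:
    network: ReactionNetwork
    trajectory: pd.DataFrame          # time series of every species (uM)
    times: np.ndarray
    aqp2_ratio: np.ndarray            # S256 phospho-ratio over time
    pka: np.ndarray                   # free-PKAC fraction over time
    controller: ErrorController

    @property
    def final_aqp2_ratio(self) -> float:
        return float(self.aqp2_ratio[-1])

    @property
    def final_pka_activity(self) -> float:
        return float(self.pka[-1])


def _initial_concentrations(net: ReactionNetwork, p: PhosphoParams,
                            include_src: bool) -> dict[str, float]:
    by_name = {species_name(ce): lab for lab, ce in net.entities.items()}
    c = {lab: 0.0 for lab in net.entities}
    holo = by_name["AKAP.PKAC.PKAR[anchor,rc]"]
    apkar = by_name["AKAP.PKAR[anchor]"]
    # all PKAC starts sequestered in the holoenzyme; PKAR is in excess
    c[holo] = p.pkac_total
    c[apkar] = p.pkar_total - p.pkac_total
    c[by_name["PDE4"]] = p.pde4_total
    c[by_name["PP2B"]] = p.pp2b_total
    c[by_name["AQP2"]] = p.aqp2_total
    if include_src:
        c[by_name["CSK"]] = p.csk_total
        c[by_name["SRC"]] = p.src_total
    return c


def run_phospho_model(params: PhosphoParams | None = None,
                      duration: float = 300.0,
                      include_src: bool = False,
                      observe_every: float = 1.0,
                      controller: ControllerConfig | None = None,
                      net: ReactionNetwork | None = None) -> PhosphoResult:
    """Integrate the well-mixed phosphorylation model.

    A single grid point; every species is one state pool; one mass-action
    module per generated reaction plus the zeroth-order cAMP influx, all
    under the adaptive controller.
    """
    p = params or PhosphoParams()
    if net is None:
        net, _ = build_signalosome(p, include_src)
    layout = StateLayout()
    labels = sorted(net.entities)
    block_of = {lab: f"s{k}" for k, lab in enumerate(labels)}
    for lab in labels:
        layout.add(block_of[lab], 1)
    y0 = layout.zeros()
    for lab, v in _initial_concentrations(net, p, include_src).items():
        y0[layout.slice_of(block_of[lab])] = v
    mods = network_modules(net, layout, block_of)
    camp_label = next(lab for lab, ce in net.entities.items()
                      if ce.size == 1 and ce.has_part("cAMP"))
    if p.camp_influx > 0:
        mods.append(Influx("camp_influx", layout,
                           layout.indices(block_of[camp_label]),
                           p.camp_influx))
    cfg = controller or ControllerConfig(dt_init=1e-3, dt_max=1.0)
    sim = Simulation(layout, y0, mods, ErrorController(cfg))

    times, rows, ratios, pkas = [], [], [], []

    def observe(t, y):
        concs = {lab: float(y[layout.slice_of(block_of[lab])][0])
                 for lab in labels}
        times.append(t)
        rows.append(concs)
        ratios.append(phospho_ratio(net, concs, "AQP2", "s256"))
        pkas.append(pka_activity(net, concs))

    sim.run_until(duration, observer=observe, observe_every=observe_every)
    traj = pd.DataFrame(rows, index=pd.Index(times, name="time"))
    traj.columns = [species_name(net.entities[lab]) for lab in traj.columns]
    return PhosphoResult(net, traj, np.asarray(times), np.asarray(ratios),
                         np.asarray(pkas), sim.controller)


# ---------------------------------------------------------------------------
# cAMP compartmentalization model
# ---------------------------------------------------------------------------

@dataclass
class CompartmentParams:
    """Gridded cAMP diffusion with a restricted vesicle-storage region.

    The storage region scales the cytoplasmic diffusivity of cAMP by the
    permeability coefficient (restriction r in the stencil) and holds the
    PDE4 sink; cAMP enters at influx nodes on the basolateral edge.
    """

    n: int = 30
    ds: float = 1.0                  # um
    D_camp: float = 32.0             # um^2/s (base cAMP diffusivity)
    permeability: float = 0.01       # restriction inside the storage region
    ring: bool = False               # membrane ring around the region
    passages: int = 2                # gaps in the ring (if present)
    influx: float = 0.4              # uM/s per influx node
    n_influx_nodes: int = 4
    pde4: float = 0.5                # uM pinned in the storage region
    kcat_hydrolysis: float = 6.0     # 1/s ("high hydrolysis")
    km_hydrolysis: float = 2.0       # uM
    storage_origin: tuple[int, int] = (10, 10)
    storage_size: int = 10
    boundary_shells: int = 3         # attenuating layer around the core


@dataclass
class CompartmentResult:
    space: SimulationSpace
    times: np.ndarray
    mean_cyto: np.ndarray
    mean_storage: np.ndarray
    mean_total: np.ndarray
    controller: ErrorController

    @property
    def fold_ratio(self) -> float:
        """Cytoplasm / storage cAMP ratio at the end of the run."""
        s = self.mean_storage[-1]
        return float(self.mean_cyto[-1] / s) if s > 0 else math.inf


def make_storage_space(p: CompartmentParams) -> SimulationSpace:
    """n x n grid with a square storage region (restriction = permeability),
    optionally ringed by a membrane with evenly spaced passages.

    The restricted block is split into a one-cell boundary layer and the
    interior: with the neighbor-r stencil, the boundary layer exchanges
    with the open cytosol at the cytosol's rate, and it is the layer's own
    low r that attenuates all flux onward into the interior.  Regional
    observables therefore report the interior, which is the region the
    permeability actually shields."""
    ids = np.zeros((p.n, p.n), dtype=int)
    i0, j0 = p.storage_origin
    k = p.storage_size
    b = min(p.boundary_shells, (k - 1) // 2)
    ids[i0:i0 + k, j0:j0 + k] = 1
    if k > 2 * b:
        ids[i0 + b:i0 + k - b, j0 + b:j0 + k - b] = 2
    space = SimulationSpace(
        ids, [Region("cytosol", 1.0),
              Region("storage-boundary", p.permeability),
              Region("storage", p.permeability)],
        p.ds)
    if not p.ring:
        space.open_h[:] = True
        space.open_v[:] = True
    else:
        # membrane only between cytosol and the restricted block
        space.open_h[:] = ~((ids[:, :-1] == 0) ^ (ids[:, 1:] == 0))
        space.open_v[:] = ~((ids[:-1, :] == 0) ^ (ids[1:, :] == 0))
        ring_faces = space.membrane_faces()
        if p.passages > len(ring_faces):
            raise ValueError("more passages than ring faces")
        if p.passages:
            stride = max(len(ring_faces) // p.passages, 1)
            for k in range(p.passages):
                space.open_passage(ring_faces[(k * stride) % len(ring_faces)])
    return space


def run_compartment_model(params: CompartmentParams | None = None,
                          duration: float = 300.0,
                          observe_every: float = 5.0,
                          controller: ControllerConfig | None = None
                          ) -> CompartmentResult:
    """cAMP diffusion + influx + storage-region hydrolysis on the grid.

    The PDE4 pool is pinned in the storage region (the signalosome is
    anchored there) and hydrolyzes cAMP with Michaelis-Menten kinetics;
    everything runs under the shared adaptive controller.
    """
    p = params or CompartmentParams()
    space = make_storage_space(p)
    storage = space.region_mask("storage")
    layout = StateLayout()
    layout.add("camp", (p.n, p.n))
    layout.add("amp", (p.n, p.n))
    layout.add("pde4", (p.n, p.n))
    y0 = layout.zeros()
    pde = layout.view(y0, "pde4")
    pde[storage] = p.pde4

    camp_idx = layout.indices("camp").reshape(p.n, p.n)
    mods: list[Module] = [
        Diffusion("camp_diffusion", layout, "camp", p.D_camp, space)]
    # influx nodes centered on the basolateral (bottom) edge
    mid = p.n // 2
    cols = [mid + k - p.n_influx_nodes // 2 for k in range(p.n_influx_nodes)]
    nodes = [camp_idx[p.n - 1, c] for c in cols]
    mods.append(Influx("camp_influx", layout, nodes, p.influx))
    si = np.nonzero(storage.ravel())[0]
    mods.append(MichaelisMentenReaction(
        "pde4_hydrolysis", layout, p.kcat_hydrolysis, p.km_hydrolysis,
        enzyme=layout.indices("pde4")[si],
        substrate=layout.indices("camp")[si],
        products=[(layout.indices("amp")[si], 1.0)]))

    # delta negligibility floor 1e-5 uM: changes below ~10 pM per step in
    # far-field cells are beneath observable resolution and are not
    # error-scored (the 5% bound applies to every scored delta)
    cfg = controller or ControllerConfig(dt_init=1e-4, dt_max=0.5,
                                         delta_floor=1e-5)
    sim = Simulation(layout, y0, mods, ErrorController(cfg))
    times, cyt, sto, tot = [], [], [], []

    def observe(t, y):
        c = layout.view(y, "camp")
        times.append(t)
        cyt.append(float(c[~storage].mean()))
        sto.append(float(c[storage].mean()))
        tot.append(float(c.mean()))

    sim.run_until(duration, observer=observe, observe_every=observe_every)
    return CompartmentResult(space, np.asarray(times), np.asarray(cyt),
                             np.asarray(sto), np.asarray(tot), sim.controller)


# ---------------------------------------------------------------------------
# Clathrin-mediated endocytosis model (1 um^2 apical patch)
# ---------------------------------------------------------------------------

@dataclass
class EndocytosisModelParams:
    """Apical membrane patch with SRC-regulated pit maturation.

    The patch is 1 um^2 of membrane (100 faces at ds = 0.1 um) loaded
    with AQP2; the PKA -> CSK -> SRC cascade runs as a well-mixed
    signalosome in the patch volume and scales the cargo collection rate
    through the active/inhibited SRC balance.
    """

    phospho: PhosphoParams = field(default_factory=PhosphoParams)
    camp_influx: float = 0.05          # uM/s into the patch volume
    aqp2_density: float = 5.0          # uM*um on the membrane
    k_p: float = 0.2                   # pits / (s * um^2)
    k_b: float = 1.0                   # 1/s base cargo addition
    t_cp: float = 30.0                 # s checkpoint deadline
    c_cp: float = 5.0                  # uM*um on the nascent vesicle
    t_m: float = 30.0                  # s maturation
    vesicle_radius: float = 0.05       # um
    clathrin_coat: float = 2.0         # uM*um added on scission
    seed: int = 1


@dataclass
class EndocytosisResult:
    times: np.ndarray
    src_ratio: np.ndarray              # SRC-Y527 phospho (inhibited) ratio
    productive: int
    abortive: int
    lifetimes_productive: list[float]
    lifetimes_abortive: list[float]
    engine: "VesicleEngine"
    controller: ErrorController

    @property
    def mean_src_ratio(self) -> float:
        return float(np.mean(self.src_ratio)) if len(self.src_ratio) else 0.0


def run_endocytosis_model(params: EndocytosisModelParams | None = None,
                          duration: float = 300.0,
                          observe_every: float = 5.0,
                          controller: ControllerConfig | None = None,
                          net: ReactionNetwork | None = None
                          ) -> EndocytosisResult:
    from mesocell.vesicle_dynamics import (EndocytosisManager,
                                           EndocytosisParams, VesicleEngine)
    p = params or EndocytosisModelParams()
    pp = replace(p.phospho, camp_influx=p.camp_influx)
    if net is None:
        net, _ = build_signalosome(pp, include_src=True)
    # strip of 2 x 100 cells at ds=0.1; the membrane between the rows is
    # the 1 um^2 apical patch
    n_faces = 100
    ds = 0.1
    ids = np.zeros((2, n_faces), dtype=int)
    ids[0, :] = 1
    space = SimulationSpace(ids, [Region("exterior"), Region("patch")], ds)
    mem = space.add_membrane("apical")
    assert abs(mem.total_area - 1.0) < 1e-9

    layout = StateLayout()
    labels = sorted(net.entities)
    block_of = {lab: f"s{k}" for k, lab in enumerate(labels)}
    for lab in labels:
        layout.add(block_of[lab], 1)
    layout.add("apical.AQP2m", n_faces)     # membrane cargo pool (uM*um)
    y0 = layout.zeros()
    for lab, v in _initial_concentrations(net, pp, True).items():
        y0[layout.slice_of(block_of[lab])] = v
    y0[layout.slice_of("apical.AQP2m")] = p.aqp2_density

    mods = network_modules(net, layout, block_of)
    camp_label = next(lab for lab, ce in net.entities.items()
                      if ce.size == 1 and ce.has_part("cAMP"))
    if pp.camp_influx > 0:
        mods.append(Influx("camp_influx", layout,
                           layout.indices(block_of[camp_label]),
                           pp.camp_influx))
    mods.append(MembraneDiffusion1D("aqp2_lateral", layout, "apical.AQP2m",
                                    D=0.05, ds=ds))

    cfg = controller or ControllerConfig(dt_init=1e-3, dt_max=0.5,
                                         delta_floor=1e-5)
    name_of = {species_name(net.entities[lab]): lab for lab in labels}
    src_active = name_of["SRC"]
    src_inhibited = name_of["P.SRC[y527]"]

    sim_box = {}

    def regulators():
        y = sim_box["sim"].y
        return (float(y[layout.slice_of(block_of[src_active])][0]),
                float(y[layout.slice_of(block_of[src_inhibited])][0]))

    mem.bind_state(layout, lambda: sim_box["sim"].y, "apical")
    # AQP2m block name must match the bind prefix convention
    ep = EndocytosisParams(
        k_p=p.k_p, k_b=p.k_b, t_cp=p.t_cp, c_cp=p.c_cp, t_m=p.t_m,
        cargo_entity="AQP2m", coat={"clathrin": p.clathrin_coat},
        vesicle_radius=p.vesicle_radius)
    engine = VesicleEngine(space, cfg, seed=p.seed)
    manager = EndocytosisManager(mem, ep, engine.rng_pits, space,
                                 regulator_conc=regulators)
    engine.endocytosis = manager
    sim = Simulation(layout, y0, mods, ErrorController(cfg), agents=engine)
    sim_box["sim"] = sim

    times, src = [], []

    def observe(t, y):
        times.append(t)
        src.append(phospho_ratio(
            net, {lab: float(y[layout.slice_of(block_of[lab])][0])
                  for lab in labels}, "SRC", "y527"))

    sim.run_until(duration, observer=observe, observe_every=observe_every)
    prod, abort = manager.counts()
    return EndocytosisResult(np.asarray(times), np.asarray(src), prod, abort,
                             manager.lifetimes_productive,
                             manager.lifetimes_abortive, engine,
                             sim.controller)


# ---------------------------------------------------------------------------
# Full recycling model
# ---------------------------------------------------------------------------

def full_influx_schedule(t: float, per_node: tuple[float, float, float] =
                         (0.4, 0.2, 0.05),
                         breaks: tuple[float, float] = (300.0, 900.0)) -> float:
    """Stepped cAMP influx per node (uM/s): 400 nM/s for the first five
    minutes, 200 nM/s until minute 15, then a basal 50 nM/s.  Scaled-down
    runs may compress the breakpoints."""
    if t < breaks[0]:
        return per_node[0]
    if t < breaks[1]:
        return per_node[1]
    return per_node[2]


@dataclass
class FullModelParams:
    """Spatiotemporal AQP2 recycling model (scaled-down desk variant).

    A 12 x 12 um cell section: apical membrane along the top, four cAMP
    influx nodes at the basolateral (bottom) edge, and a
    diffusion-restricted perinuclear storage region holding the AKAP
    signalosome and the AQP2 vesicle pool.  Actin filaments guide
    departing vesicles to the apical membrane; microtubules return
    endocytosed vesicles to storage.  The recycling variant accelerates
    CSK/SRC dephosphorylation so productive endocytosis resumes.
    """

    phospho: PhosphoParams = field(default_factory=PhosphoParams)
    n: int = 12
    ds: float = 1.0
    D_camp: float = 32.0
    permeability: float = 0.01
    storage_origin: tuple[int, int] = (7, 4)
    storage_size: int = 4
    exchange_rate: float = 5.0          # 1/s signalosome <-> storage cAMP
    influx_breaks: tuple[float, float] = (300.0, 900.0)
    n_vesicles: int = 5
    vesicle_radius: float = 0.3
    vesicle_aqp2: float = 5.0           # uM*um membrane density
    vesicle_rsnare: float = 1.0
    D_vesicle: float = 0.13             # um^2/s
    departure_threshold: float = 0.75   # S256 phospho-ratio trigger
    basal_ratio: float = 0.46
    v_actin: float = 0.8                # um/s motor speed
    v_microtubule: float = 0.8
    attach_distance: float = 0.5
    fusion: "FusionParams | None" = None
    qsnare_density: float = 2.0         # uM*um on the apical membrane
    # endocytosis at the apical membrane
    k_p: float = 0.05
    k_b: float = 0.5
    t_cp: float = 20.0
    c_cp: float = 2.0
    t_m: float = 15.0
    clathrin_coat: float = 2.0
    boost_speed: float = 0.4            # um/s per (uM*um) clathrin
    boost_duration: float = 2.0
    permeability_factor: float = 0.04   # permeability per (uM*um) AQP2
    recycling: bool = False             # accelerated SRC/CSK reactivation
    recycling_dephos: float = 1.0       # 1/s in the recycling variant
    seed: int = 1


@dataclass
class FullModelResult:
    times: np.ndarray
    permeability: np.ndarray            # factor x mean apical AQP2 density
    camp_cyto: np.ndarray
    camp_storage: np.ndarray
    pka: np.ndarray                     # free-PKAC fraction
    src_ratio: np.ndarray               # inhibited-SRC fraction
    fusion_events: list[tuple[float, int]]
    productive_pits: int
    abortive_pits: int
    engine: "VesicleEngine"
    controller: ErrorController
    aqp2_total_trace: np.ndarray        # conservation check (uM*um^3)


def run_full_model(params: FullModelParams | None = None,
                   duration: float = 180.0,
                   observe_every: float = 2.0,
                   net: ReactionNetwork | None = None) -> FullModelResult:
    """Integrate the coupled recycling model.

    The rule-generated signalosome runs as a well-mixed pool anchored in
    the storage region, exchanging cAMP with the restricted grid cells;
    each vesicle's AQP2-S256 phospho-ratio follows pseudo-first-order
    kinase/phosphatase kinetics driven by the signalosome's free PKAC and
    PP2B (total AQP2 rides on vesicles, membrane, and pits only, so
    species amounts are conserved exactly across transport, fusion, and
    endocytosis).
    """
    from mesocell.vesicle_dynamics import (BoostSpec, EndocytosisManager,
                                           EndocytosisParams, FusionManager,
                                           FusionParams, MotorSpec,
                                           StateChangeSpec, VesicleEngine)
    from mesocell.agents import Filament, Vesicle

    p = params or FullModelParams()
    pp = replace(p.phospho, aqp2_total=0.0, camp_influx=0.0)
    if p.recycling:
        pp = replace(pp, k_csk_dephos=p.recycling_dephos,
                     k_src_dephos=p.recycling_dephos)
    if net is None:
        net, _ = build_signalosome(pp, include_src=True)

    # ---- space: exterior strip / cytosol / restricted storage block ----
    n = p.n
    ids = np.zeros((n, n), dtype=int)
    ids[0, :] = 3                                    # exterior above apical
    i0, j0 = p.storage_origin
    k = p.storage_size
    ids[i0:i0 + k, j0:j0 + k] = 1
    if k > 2:
        ids[i0 + 1:i0 + k - 1, j0 + 1:j0 + k - 1] = 2
    space = SimulationSpace(
        ids, [Region("cytosol", 1.0),
              Region("storage-boundary", p.permeability),
              Region("storage", p.permeability),
              Region("exterior", 1.0)], p.ds)
    # restriction realized by r alone; only the apical membrane blocks flux
    space.open_h[:] = True
    space.open_v[:] = True
    space.open_v[0, :] = False                       # apical membrane faces
    apical_faces = space.membrane_faces()
    mem = space.add_membrane("apical", apical_faces)
    storage_cells = (ids == 1) | (ids == 2)

    # ---- state layout ----
    layout = StateLayout()
    labels = sorted(net.entities)
    block_of = {lab: f"s{q}" for q, lab in enumerate(labels)}
    for lab in labels:
        layout.add(block_of[lab], 1)
    layout.add("camp", (n, n))
    layout.add("amp", (n, n))
    for ent in ("AQP2", "QSNARE", "RSNARE", "clathrin"):
        layout.add(f"apical.{ent}", mem.n_faces)
    y0 = layout.zeros()
    for lab, v in _initial_concentrations(net, pp, True).items():
        y0[layout.slice_of(block_of[lab])] = v
    y0[layout.slice_of("apical.QSNARE")] = p.qsnare_density

    name_of = {species_name(net.entities[lab]): lab for lab in labels}
    camp_pool = block_of[name_of["cAMP"]]
    pkac_free = layout.slice_of(block_of[name_of["PKAC"]])
    pp2b_free = layout.slice_of(block_of[name_of["PP2B"]])
    src_active = layout.slice_of(block_of[name_of["SRC"]])
    src_inhib = layout.slice_of(block_of[name_of["P.SRC[y527]"]])

    # ---- concentration modules ----
    mods = network_modules(net, layout, block_of)
    mods.append(Diffusion("camp_diffusion", layout, "camp", p.D_camp, space))
    camp_idx = layout.indices("camp").reshape(n, n)
    mid = n // 2
    nodes = [camp_idx[n - 1, mid + q - 2] for q in range(4)]
    mods.append(Influx("camp_influx", layout, nodes,
                       lambda t: full_influx_schedule(t, breaks=p.influx_breaks)))
    mods.append(CompartmentExchange(
        "storage_exchange", layout, layout.indices(camp_pool),
        camp_idx[storage_cells], p.exchange_rate))
    mods.append(MembraneDiffusion1D("aqp2_lateral", layout, "apical.AQP2",
                                    D=0.05, ds=p.ds))

    # ---- agent layer ----
    cfg = ControllerConfig(dt_init=1e-4, dt_max=0.25, delta_floor=1e-5)
    sx, sy = (j0 + k / 2.0) * p.ds, (i0 + k / 2.0) * p.ds
    actin = [Filament([(sx - 1.0 + 2.0 * q, sy), (sx - 1.0 + 2.0 * q, 1.2)],
                      kind="actin") for q in range(2)]
    mts = [Filament([(sx - 2.0 + 4.0 * q, 1.4), (sx - 2.0 + 4.0 * q, sy)],
                    kind="microtubule") for q in range(2)]
    state_changes = [
        StateChangeSpec(("departing",), "actin_attached", "near_filament",
                        value=p.attach_distance, filament_kind="actin"),
        StateChangeSpec(("scissioned",), "returning", "chance", value=0.5),
        StateChangeSpec(("returning",), "microtubule_attached",
                        "near_filament", value=p.attach_distance,
                        filament_kind="microtubule"),
    ]
    motors = [
        MotorSpec("actin", p.v_actin, toward_plus=True,
                  applicable_states=("actin_attached",),
                  detach_state="tethered"),
        MotorSpec("microtubule", p.v_microtubule, toward_plus=True,
                  applicable_states=("microtubule_attached",),
                  detach_state="in_storage"),
    ]
    engine = VesicleEngine(
        space, cfg, seed=p.seed, brownian_D=p.D_vesicle,
        brownian_states=("in_storage", "departing", "tethered", "scissioned",
                         "returning"),
        motors=motors,
        boost=BoostSpec(p.boost_speed, "clathrin",
                        applicable_states=("scissioned",)),
        state_changes=state_changes)
    engine.filaments = actin + mts

    rng_init = np.random.default_rng(np.random.SeedSequence([p.seed, 11]))
    for q in range(p.n_vesicles):
        pos = (np.array([j0, i0]) + 0.6 + rng_init.random(2) * (k - 1.2)) * p.ds
        v = Vesicle(-1, pos, p.vesicle_radius, state="in_storage",
                    membrane={"AQP2": p.vesicle_aqp2,
                              "RSNARE": p.vesicle_rsnare})
        v.aqp2_ratio = p.basal_ratio
        engine.add_vesicle(v)

    mem.bind_state(layout, lambda: sim_box["sim"].y, "apical")
    fus = p.fusion or FusionParams(t_f=1.0, d_a=0.4, snare_q="QSNARE",
                                   snare_r="RSNARE", n_p=3)
    engine.fusion = FusionManager(mem, fus, space, layout,
                                  eligible_states=("tethered",))
    ep = EndocytosisParams(
        k_p=p.k_p, k_b=p.k_b, t_cp=p.t_cp, c_cp=p.c_cp, t_m=p.t_m,
        cargo_entity="AQP2", coat={"clathrin": p.clathrin_coat,
                                   "RSNARE": p.vesicle_rsnare},
        vesicle_radius=p.vesicle_radius)

    def regulators():
        y = sim_box["sim"].y
        return (float(y[src_active][0]), float(y[src_inhib][0]))

    engine.endocytosis = EndocytosisManager(mem, ep, engine.rng_pits, space,
                                            regulator_conc=regulators)

    # ---- per-step qualitative hook: phospho-ratio kinetics, departure ----
    def custom_step(eng, t, dt, y):
        c_free = float(y[pkac_free][0])
        c_pp2b = float(y[pp2b_free][0])
        # pseudo-first-order rates from the signalosome state (same branch
        # ratios as the full network: 3/4 of kinase encounters and 2/3 of
        # phosphatase encounters are productive)
        kp = 0.75 * pp.k_sub_bind * c_free
        kd = (2.0 / 3.0) * pp.k_pp2b_bind * c_pp2b
        lam = kp + kd
        rho_inf = kp / lam if lam > 0 else 0.0
        decay = math.exp(-lam * dt) if lam > 0 else 1.0
        for v in eng._ordered():
            rho = getattr(v, "aqp2_ratio", p.basal_ratio)
            v.aqp2_ratio = rho_inf + (rho - rho_inf) * decay
            if v.state == "in_storage" and \
                    v.aqp2_ratio >= p.departure_threshold:
                v.state = "departing"

    engine.custom_step = custom_step

    sim_box = {}
    sim = Simulation(layout, y0, mods, ErrorController(cfg), agents=engine)
    sim_box["sim"] = sim

    times, perm, ccy, cst, pka_tr, src_tr, aqp_tot = ([] for _ in range(7))

    def total_aqp2(y):
        tot = mem.total_amount("AQP2")
        for v in engine.vesicles.values():
            tot += v.membrane_amount("AQP2")
        if engine.endocytosis is not None:
            for pit in engine.endocytosis.pits:
                tot += pit.cargo.get("AQP2", 0.0)
        return tot

    def observe(t, y):
        times.append(t)
        aq = layout.view(y, "apical.AQP2")
        perm.append(p.permeability_factor * float(aq.mean()))
        c = layout.view(y, "camp")
        ccy.append(float(c[ids == 0].mean()))
        cst.append(float(c[storage_cells].mean()))
        concs = {lab: float(y[layout.slice_of(block_of[lab])][0])
                 for lab in labels}
        pka_tr.append(pka_activity(net, concs))
        src_tr.append(phospho_ratio(net, concs, "SRC", "y527"))
        aqp_tot.append(total_aqp2(y))

    sim.run_until(duration, observer=observe, observe_every=observe_every)
    prod, abort = engine.endocytosis.counts()
    return FullModelResult(
        np.asarray(times), np.asarray(perm), np.asarray(ccy),
        np.asarray(cst), np.asarray(pka_tr), np.asarray(src_tr),
        list(engine.fusion.completed), prod, abort, engine, sim.controller,
        np.asarray(aqp_tot))
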