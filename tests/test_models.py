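"""Bundled model configurations: structure and fast sanity behaviors.

The quantitative model-level checks (basal phospho-ratio, stimulation
response, compartmentalization fold-ratio, pit statistics) live in the
acceptance suite; these tests cover structure and cheap controls.
"""

import numpy as np
import pytest
from dataclasses import replace

from mesocell.models import (CompartmentParams, FullModelParams,
                             PhosphoParams, full_influx_schedule,
                             make_storage_space, phospho_ratio, pka_activity,
                             run_compartment_model, run_full_model,
                             run_phospho_model, species_name)


class TestSignalosomeStructure:
    def test_pkac_release_requires_both_camp_sites(self, signalosome):
        """No generated reaction releases PKAC from a holoenzyme carrying
        fewer than two cAMP."""
        for rx in signalosome.reactions:
            if rx.rule != "pkac_release":
                continue
            (sub,) = rx.substrates
            assert signalosome.entities[sub].count_part("cAMP") == 2

    def test_phospho_pkar_binds_pkac_only_through_weak_rule(self, signalosome):
        for rx in signalosome.reactions:
            if rx.rule == "pkac_bind":
                for s in rx.substrates:
                    ce = signalosome.entities[s]
                    if ce.has_part("PKAR"):
                        assert not ce.site_edges("rp")
            if rx.rule == "pkac_bind_phospho":
                for s in rx.substrates:
                    ce = signalosome.entities[s]
                    if ce.has_part("PKAR"):
                        assert ce.site_edges("rp")

    def test_phospho_pde4_uses_enhanced_hydrolysis_rate(self, signalosome,
                                                        phospho_params):
        rates = {}
        for rx in signalosome.reactions:
            if rx.rule in ("hydrolysis", "hydrolysis_phospho"):
                rates[rx.rule] = dict(rx.rate_constants)["k"]
        assert rates["hydrolysis"] == phospho_params.k_hydrolysis
        assert rates["hydrolysis_phospho"] == \
            phospho_params.k_hydrolysis_phospho
        assert rates["hydrolysis_phospho"] > rates["hydrolysis"]

    def test_observable_helpers_on_synthetic_state(self, signalosome):
        by_name = {species_name(ce): lab
                   for lab, ce in signalosome.entities.items()}
        concs = {lab: 0.0 for lab in signalosome.entities}
        concs[by_name["AQP2"]] = 1.0
        concs[by_name["AQP2.P[s256]"]] = 3.0
        assert phospho_ratio(signalosome, concs, "AQP2", "s256") == \
            pytest.approx(0.75)
        concs = {lab: 0.0 for lab in signalosome.entities}
        concs[by_name["PKAC"]] = 1.0
        concs[by_name["AKAP.PKAC.PKAR[anchor,rc]"]] = 3.0
        assert pka_activity(signalosome, concs) == pytest.approx(0.25)


class TestPhosphoModelControls:
    def test_no_stimulus_stays_at_dephosphorylated_fixed_point(self,
                                                               signalosome):
        res = run_phospho_model(replace(PhosphoParams(), camp_influx=0.0),
                                duration=60.0, net=signalosome)
        assert res.final_pka_activity == pytest.approx(0.0, abs=1e-9)
        assert res.final_aqp2_ratio == pytest.approx(0.0, abs=1e-9)

    def test_mass_of_protein_pools_is_conserved(self, signalosome,
                                                phospho_params):
        res = run_phospho_model(duration=30.0, net=signalosome)
        final = res.trajectory.iloc[-1]
        for part, total in [("PKAR", phospho_params.pkar_total),
                            ("PKAC", phospho_params.pkac_total),
                            ("AQP2", phospho_params.aqp2_total),
                            ("PP2B", phospho_params.pp2b_total),
                            ("PDE4", phospho_params.pde4_total)]:
            got = sum(ce.count_part(part) * final[species_name(ce)]
                      for ce in signalosome.entities.values())
            assert got == pytest.approx(total, rel=1e-6)


class TestCompartmentGeometry:
    def test_storage_space_regions_and_restriction(self):
        p = CompartmentParams(n=20, storage_origin=(6, 6), storage_size=8,
                              permeability=0.05)
        space = make_storage_space(p)
        storage = space.region_mask("storage")
        boundary = space.region_mask("storage-boundary")
        assert storage.sum() == 4           # 2x2 core of the 8x8 block
        assert boundary.sum() == 60         # three-cell attenuating shell
        assert np.all(space.restriction[storage | boundary] == 0.05)
        assert not space.membrane_faces()   # restriction-only by default

    def test_membrane_ring_has_exactly_the_requested_passages(self):
        p = CompartmentParams(n=20, storage_origin=(6, 6), storage_size=8,
                              ring=True, passages=2)
        space = make_storage_space(p)
        # 8x8 block perimeter = 32 faces, minus 2 opened passages
        assert len(space.membrane_faces()) == 30

    def test_zero_influx_keeps_all_regions_at_zero(self):
        p = CompartmentParams(n=12, storage_origin=(4, 4), storage_size=4,
                              influx=0.0)
        res = run_compartment_model(p, duration=5.0, observe_every=5.0)
        assert res.mean_cyto[-1] == 0.0
        assert res.mean_storage[-1] == 0.0


class TestFullModelControls:
    def test_printed_influx_schedule_steps(self):
        assert full_influx_schedule(0.0) == pytest.approx(0.4)
        assert full_influx_schedule(299.9) == pytest.approx(0.4)
        assert full_influx_schedule(300.1) == pytest.approx(0.2)
        assert full_influx_schedule(899.9) == pytest.approx(0.2)
        assert full_influx_schedule(900.1) == pytest.approx(0.05)

    def test_no_vesicles_means_constant_basal_permeability(self):
        p = FullModelParams(n_vesicles=0, k_p=0.0)
        res = run_full_model(p, duration=5.0, observe_every=1.0)
        assert np.all(res.permeability == res.permeability[0])
        assert res.permeability[0] == 0.0


class TestFullModelVariants:
    """Scaled-down activation vs recycling runs (150 s, 12 x 12 um)."""

    @pytest.fixture(scope="class")
    def variants(self):
        runs = {}
        for rec in (False, True):
            runs[rec] = run_full_model(FullModelParams(recycling=rec),
                                       duration=150.0, observe_every=2.0)
        return runs

    def test_activation_permeability_rises_in_discrete_jumps(self, variants):
        res = variants[False]
        jumps = np.diff(res.permeability)
        assert res.permeability[0] == 0.0
        assert (jumps > 1e-4).sum() >= 3        # individual fusion events
        assert len(res.fusion_events) >= 1
        # stays elevated while endocytosis is suppressed
        assert res.permeability[-1] >= 0.5 * res.permeability.max()

    def test_basal_phase_holds_vesicles_below_departure_threshold(self,
                                                                  variants):
        res = variants[False]
        # no vesicle departs before cAMP reaches the storage signalosome
        early = res.times < 20.0
        assert np.all(res.permeability[early] == 0.0)

    def test_recycling_variant_reactivates_src_and_returns_aqp2(self,
                                                                variants):
        act, rec = variants[False], variants[True]
        # accelerated dephosphorylation reactivates SRC
        assert rec.src_ratio[-1] < 0.5 * act.src_ratio[-1]
        # recovered endocytosis pulls AQP2 back off the apical membrane
        assert rec.permeability[-1] < act.permeability[-1]
        states = {v.state for v in rec.engine.vesicles.values()}
        assert states & {"microtubule_attached", "in_storage", "returning"}

    def test_total_aqp2_is_conserved_through_the_whole_cycle(self, variants):
        for res in variants.values():
            tot = res.aqp2_total_trace
            np.testing.assert_allclose(tot, tot[0], rtol=1e-9)
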