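"""Structure of the reaction network: fragments, composition, validation."""

import numpy as np
import pytest

from chondrosim import (
    CompositionError,
    build_ecm_module,
    build_il1_module,
    build_integrated_model,
    build_osm_module,
    compose_integrated_model,
    simulate_ode,
    target_genes,
    validate_model,
)
from chondrosim.network import basal_transcription_genes
from chondrosim.ode import reaction_fluxes

from conftest import small_model


class TestFragments:
    def test_homodimer_targets_exactly_eight_genes(self):
        frag = build_il1_module()
        assert target_genes(frag, "pcJun_dimer") == {
            "cJun", "MMP1", "MMP3", "MMP13", "ADAMTS4", "PP4", "DUSP16", "MKP1"
        }

    def test_ap1_targets_exactly_twelve_genes(self):
        frag = build_osm_module()
        assert target_genes(frag, "AP1") == {
            "cFos", "cJun", "MMP1", "MMP3", "MMP13", "ADAMTS4",
            "DUSP16", "PP4", "MKP1", "Sp1", "TIMP1", "TIMP3"
        }

    def test_basal_transcription_is_cjun_timp1_timp3(self):
        frag = build_il1_module()
        assert basal_transcription_genes(frag) == {"cJun", "TIMP1", "TIMP3"}

    def test_ap1_assembly_is_reversible(self):
        frag = build_osm_module()
        ids = {r.id for r in frag.reactions}
        assert "bind_ap1" in ids and "unbind_ap1" in ids

    def test_no_ligand_means_no_downstream_flux(self):
        """With zero IL-1 every reaction strictly downstream of the receptor
        has zero rate at t=0."""
        frag = build_il1_module()
        m = compose_integrated_model([frag])
        flux = reaction_fluxes(m, m.initial_state())
        rid = [r.id for r in m.reactions]
        for downstream in ("bind_il1", "phos_irak2", "phos_jnk", "phos_p38",
                           "phos_cjun", "dim_cjun", "tx_MMP1_lo"):
            assert flux[rid.index(downstream)] == 0.0

    def test_osm_alone_no_cfos_transcription_at_t0(self):
        frag = build_osm_module()
        m = compose_integrated_model([build_il1_module(), frag])
        flux = reaction_fluxes(m, m.initial_state())
        rid = [r.id for r in m.reactions]
        assert flux[rid.index("tx_cFos_stat")] == 0.0
        assert flux[rid.index("tx_cFos_hi")] == 0.0

    def test_il1_fragment_alone_has_no_collagen_species(self):
        m = compose_integrated_model([build_il1_module()])
        ids = {s.id for s in m.species}
        assert "CollFrag" not in ids and "AggColl" not in ids

    def test_ecm_fragment_collagen_reactions_conserve_matrix(self):
        """Stoichiometry-matrix left-null-vector oracle for the matrix pools."""
        m = compose_integrated_model([build_ecm_module()])
        S = m.stoichiometry_matrix()
        idx = m.species_index()
        for members in (("AggColl", "Coll", "CollFrag"), ("AggColl", "AggFrag")):
            v = np.zeros(len(m.species))
            for mem in members:
                v[idx[mem]] = 1.0
            assert np.allclose(v @ S, 0.0)

    def test_isolated_active_mmp_pool_halves_in_30h(self):
        """An active MMP-1 pool with no synthesis decays with ~30 h half-life."""
        m = compose_integrated_model([build_ecm_module()])
        m = m.with_initial_amounts({"MMP1": 1000, "TIMP1": 0, "TIMP3": 0})
        tc = simulate_ode(m, horizon_h=30.0, grid_h=np.array([0.0, 15.0, 30.0]))
        assert tc["MMP1"][-1] == pytest.approx(500.0, rel=1e-3)


class TestComposition:
    def test_integrated_model_counts_are_fixed(self, model):
        assert len(model.species) == 71
        assert len(model.reactions) == 139
        assert len(model.parameters) == 107

    def test_mmp1_mmp13_transcription_ratio_is_ten_in_both_contexts(self, model):
        pm = model.parameter_map()
        assert pm["k_tx_MMP1_lo"].value / pm["k_tx_MMP13_lo"].value == pytest.approx(10)
        assert pm["k_tx_MMP1_hi"].value / pm["k_tx_MMP13_hi"].value == pytest.approx(10)
        # equal mRNA decay: one shared constant
        decays = {r.rate_constant for r in model.reactions
                  if r.id in ("deg_mRNA_MMP1", "deg_mRNA_MMP13")}
        assert decays == {"k_deg_mrna"}

    def test_bad_ratio_is_rejected(self):
        frags = [build_il1_module(), build_osm_module(), build_ecm_module()]
        with pytest.raises(CompositionError, match="ratio"):
            compose_integrated_model(frags, params={"k_tx_MMP13_hi": 1.0})

    def test_mismatched_shared_species_is_a_composition_error(self):
        from dataclasses import replace

        il1 = build_il1_module()
        osm = build_osm_module()
        osm.species = [replace(s, initial_amount=999) if s.id == "TRAF6" else s
                       for s in osm.species]
        with pytest.raises(CompositionError, match="TRAF6"):
            compose_integrated_model([il1, osm])

    def test_shared_non_interface_species_is_rejected(self):
        il1 = build_il1_module()
        osm = build_osm_module()
        il1.interface_species = [s for s in il1.interface_species if s != "pp38"]
        with pytest.raises(CompositionError, match="pp38"):
            compose_integrated_model([il1, osm])

    def test_duplicate_reaction_id_is_rejected(self):
        a, b = build_il1_module(), build_il1_module()
        a.interface_species = sorted(a.species_ids())
        b.interface_species = sorted(b.species_ids())
        with pytest.raises(CompositionError, match="duplicate reaction"):
            compose_integrated_model([a, b])


class TestValidation:
    def test_shipped_model_has_clean_diagnostics(self, model):
        assert validate_model(model) == []

    def test_unit_order_mismatch_is_reported(self):
        m = small_model(
            species=[("A", 5, "protein"), ("B", 5, "protein"), ("C", 0, "protein")],
            reactions=[("bind", {"A": 1, "B": 1}, {"C": 1}, (), "k")],
            parameters=[("k", 1.0, "per_second")],
        )
        problems = validate_model(m)
        assert any("unit" in p or "order" in p for p in problems)

    def test_conservation_violation_is_reported(self):
        m = small_model(
            species=[("AggColl", 100, "matrix_component"),
                     ("Coll", 0, "matrix_component"),
                     ("CollFrag", 0, "fragment")],
            reactions=[("magic", {}, {"CollFrag": 1}, (), "k")],
            parameters=[("k", 1.0, "per_second")],
        )
        m.conserved_pools = {"collagen": ["AggColl", "Coll", "CollFrag"]}
        problems = validate_model(m)
        assert any("conservation" in p for p in problems)

    def test_orphan_species_is_reported(self):
        m = small_model(
            species=[("A", 1, "protein"), ("Lonely", 1, "protein")],
            reactions=[("deg", {"A": 1}, {}, (), "k")],
            parameters=[("k", 1.0, "per_second")],
        )
        assert any("Lonely" in p for p in validate_model(m))

    def test_species_table_roundtrips_counts(self, model):
        df = model.species_table()
        assert set(df.columns) == {"id", "display_name", "compartment",
                                   "initial_amount", "role"}
        assert len(df) == len(model.species)
        assert df.set_index("id").loc["TIMP1", "initial_amount"] == 200
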