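"""Hydrogen-bond / salt-bridge / stacking detection, stable-pair
statistics and interface region classification."""

import numpy as np
import pytest

from pfklab.interactions import (CapabilityError, HBondCriteria,
                                 InteractionCriteria, SaltBridgeCriteria,
                                 StackingCriteria, classify_interface_regions,
                                 detect_interactions, stable_pairs,
                                 subsample_frames)
from pfklab.synthetic import gen_interaction_fixture, gen_toy_assembly
from conftest import make_structure, merge_structures


class TestDetectInteractions:
    def test_bidentate_asn_pair_gives_two_hydrogen_bonds(self):
        s = gen_interaction_fixture("hb_bidentate")
        records = detect_interactions(s, "hydrogen_bond")
        assert len(records) == 2
        for rec in records:
            assert rec.distance <= 0.35
            assert rec.angle >= 120.0
            assert {rec.residue_a[2], rec.residue_b[2]} == {"ASN"}

    def test_salt_bridge_inside_cutoff_only(self):
        s = gen_interaction_fixture("salt_bridge")
        records = detect_interactions(s, "salt_bridge")
        assert len(records) == 1
        assert records[0].distance == pytest.approx(0.37, abs=1e-6)
        # widen the gap beyond 0.40 nm: no detection
        far = s.with_coords(s.coords + np.where(
            (s.chain_ids == "B")[:, None], [0.25, 0, 0], [0, 0, 0]))
        assert detect_interactions(far, "salt_bridge") == []

    def test_salt_bridge_fixture_has_no_other_hydrogen_bonds(self):
        s = gen_interaction_fixture("salt_bridge")
        hbs = detect_interactions(s, criteria=InteractionCriteria())
        assert all(r.type == "salt_bridge" for r in hbs)

    def test_parallel_stack_detected_with_subtype(self):
        s = gen_interaction_fixture("stack")
        records = detect_interactions(s, "aromatic_stacking")
        assert len(records) == 1
        assert records[0].subtype == "parallel"
        assert records[0].distance == pytest.approx(0.45, abs=1e-6)

    def test_t_shaped_stack_classified(self):
        s = gen_interaction_fixture("stack")
        # rotate ring B by 90 degrees about x through its centroid
        coords = s.coords.copy()
        mask = s.chain_ids == "B"
        centroid = coords[mask].mean(axis=0)
        rel = coords[mask] - centroid
        rot = np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0.0]])
        coords[mask] = rel @ rot.T + centroid
        records = detect_interactions(s.with_coords(coords),
                                      "aromatic_stacking")
        assert len(records) == 1
        assert records[0].subtype == "t_shaped"

    def test_none_fixture_and_empty_structure(self):
        assert detect_interactions(gen_interaction_fixture("none")) == []
        empty = make_structure(1).subset(np.array([], dtype=int))
        assert detect_interactions(empty) == []

    def test_capability_error_on_bead_structure(self):
        beads = make_structure(5, name="BB")
        with pytest.raises(CapabilityError):
            detect_interactions(beads, "hydrogen_bond")

    def test_records_satisfy_their_criteria(self):
        crit = InteractionCriteria()
        for kind in ("hb_bidentate", "salt_bridge", "stack"):
            for rec in detect_interactions(gen_interaction_fixture(kind),
                                           criteria=crit):
                if rec.type == "hydrogen_bond":
                    assert rec.distance <= crit.hb.max_da_distance
                elif rec.type == "salt_bridge":
                    assert rec.distance <= crit.sb.max_no_distance
                else:
                    assert rec.distance <= crit.stack.max_centroid_distance

    @pytest.mark.parametrize("shrink", [0.9, 0.7, 0.5])
    def test_shrinking_distance_criteria_is_monotone(self, shrink):
        s = merge_structures(
            gen_interaction_fixture("hb_bidentate"),
            gen_interaction_fixture("salt_bridge"),
            gen_interaction_fixture("stack"))
        full = InteractionCriteria()
        tight = InteractionCriteria(
            hb=HBondCriteria(max_da_distance=0.35 * shrink),
            sb=SaltBridgeCriteria(max_no_distance=0.40 * shrink),
            stack=StackingCriteria(max_centroid_distance=0.55 * shrink))
        n_full = len(detect_interactions(s, criteria=full))
        n_tight = len(detect_interactions(s, criteria=tight))
        assert n_tight <= n_full


class TestStablePairs:
    PAIR_A = (("A", 702, "ASN"), ("B", 702, "ASN"))

    def _records(self, present_frames, pair=None):
        from pfklab.interactions import InteractionRecord
        pair = pair or self.PAIR_A
        return [InteractionRecord(type="hydrogen_bond", residue_a=pair[0],
                                  residue_b=pair[1], frame=f, distance=0.3)
                for f in present_frames]

    def test_always_present_pair_has_unit_occupancy(self):
        out = stable_pairs(self._records(range(48)), 48, 0.5)
        assert len(out) == 1
        assert out[0][2] == 1.0

    def test_rare_pair_excluded(self):
        assert stable_pairs(self._records(range(10)), 48, 0.5) == []

    def test_occupancy_matches_direct_counting(self, rng):
        present = sorted(rng.choice(48, size=20, replace=False))
        out = stable_pairs(self._records(present), 48,
                           persistence_threshold=1e-9)
        assert out[0][2] == pytest.approx(len(present) / 48)

    def test_threshold_extremes(self):
        recs = self._records(range(24))  # half the frames
        assert len(stable_pairs(recs, 48, persistence_threshold=1e-9)) == 1
        assert stable_pairs(recs, 48, persistence_threshold=1.0) == []

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            stable_pairs([], 48, 0.0)
        with pytest.raises(ValueError):
            stable_pairs([], 48, 1.5)

    def test_subsample_frames_evenly_spaced(self):
        idx = subsample_frames(1000, 16)
        assert len(idx) == 16
        assert idx[0] == 0 and idx[-1] == 999
        spacings = np.diff(idx)
        assert spacings.max() - spacings.min() <= 1


class TestClassifyInterfaceRegions:
    """Rule-table behavior on a constructed dimer: a chain of beads packed
    against a partner chain, with known burial before/after."""

    def _dimer(self):
        # monomer A: 3x3 grid of beads; complexation adds chain B stacked
        # against one face
        n_side = 3
        coords_a = np.array([[i * 0.4, j * 0.4, 0.0]
                             for i in range(n_side) for j in range(n_side)])
        a = make_structure(9, chain_id="A", resname="ALA", name="CA",
                           coords=coords_a)
        coords_b = coords_a + np.array([0.0, 0.0, 0.45])
        b = make_structure(9, chain_id="B", resname="ALA", name="CA",
                           coords=coords_b)
        a.radii[:] = 0.2
        b.radii[:] = 0.2
        return a, merge_structures(a, b)

    def test_regions_partition_residue_set(self):
        mono, cplx = self._dimer()
        out = classify_interface_regions(mono, cplx, monomer_chain="A",
                                         rsasa_threshold=0.25)
        assert set(out.regions) == {("A", i) for i in range(1, 10)}
        valid = {"core", "support", "rim_interacting", "rim_nis",
                 "surface", "interior"}
        assert set(out.regions.values()) <= valid

    def test_interface_residues_lose_sasa(self):
        mono, cplx = self._dimer()
        out = classify_interface_regions(mono, cplx, monomer_chain="A")
        iface = {"core", "support", "rim_interacting"}
        for key, region in out.regions.items():
            if region in iface:
                assert out.complex_rsasa[key] <= out.monomer_rsasa[key] + 1e-9

    def test_rule_table_on_synthetic_rsasa(self):
        """Direct rule check: support/core/rim assignments follow the
        burial thresholds."""
        from pfklab.interactions import RegionAssignment
        # emulate classification outcomes through the real pipeline by
        # reusing the dimer and checking consistency with the rule table
        mono, cplx = self._dimer()
        out = classify_interface_regions(mono, cplx, monomer_chain="A",
                                         rsasa_threshold=0.25)
        for key, region in out.regions.items():
            m, c = out.monomer_rsasa[key], out.complex_rsasa[key]
            if region == "support":
                assert m < 0.25
            elif region == "core":
                assert m >= 0.25 and c < 0.25
            elif region == "rim_interacting":
                assert m >= 0.25 and c >= 0.25
            elif region == "interior":
                assert m < 0.25

    def test_numbering_mismatch_rejected(self):
        mono, cplx = self._dimer()
        shifted = make_structure(9, chain_id="A", resname="ALA", name="CA",
                                 start_resnum=100)
        shifted.radii[:] = 0.2
        with pytest.raises(ValueError, match="residue set"):
            classify_interface_regions(shifted, cplx, monomer_chain="A")


class TestToyAssembly:
    def test_interface_lists_selectable(self):
        from pfklab.core import ResidueSelection, select_residues
        s = gen_toy_assembly(interface1=(3, 4, 5), interface2=(12, 13))
        sel = ResidueSelection(tuple(("A", r, r) for r in (3, 4, 5)))
        assert select_residues(s, sel).n_residues == 3

    def test_deterministic_per_seed(self):
        a = gen_toy_assembly(seed=9)
        b = gen_toy_assembly(seed=9)
        np.testing.assert_array_equal(a.coords, b.coords)
        c = gen_toy_assembly(seed=10)
        assert not np.array_equal(a.coords, c.coords)

    def test_stacked_assemblies_match_contact_oracle(self):
        from pfklab.contacts import ContactParameters, count_contacts
        from tests_oracles import brute_pairs
        a = gen_toy_assembly(seed=0)
        b = gen_toy_assembly(seed=0, center=np.array([0.0, 0.0, 7.5]))
        coords = np.vstack([a.coords, b.coords])
        ia = np.arange(a.n_particles)
        ib = np.arange(a.n_particles, a.n_particles + b.n_particles)
        got = count_contacts(coords, ia, ib, ContactParameters())
        assert got == brute_pairs(coords, ia, ib, 0.7)
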