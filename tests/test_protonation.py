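"""Microstate rules, hydrogen construction geometry and water orientation."""

import numpy as np
import pytest

from protonwire._geom import angle_deg, unit
from protonwire.protonation import (
    MetalSiteConstraints,
    ProtonationConfig,
    assign_microstates,
    orient_waters,
    place_hydrogens,
    protonate,
)
from conftest import (
    assemble,
    make_arginine_head,
    make_histidine,
    make_nickel,
    make_residue,
    make_water,
)


def variant_of(variants, residue):
    return next(v for v in variants if v.residue is residue)


class TestMicrostateRules:
    def test_isolated_lysine_is_cationic(self):
        lys = make_residue("LYS", [("CE", "C", (0, 0, 0)), ("NZ", "N", (1.49, 0, 0))])
        s = assemble(chains={"A": [lys]})
        v = variant_of(assign_microstates(s), lys)
        assert v.code == "LYS+" and v.formal_charge == +1

    def test_acidic_residues_deprotonated_by_default(self):
        asp = make_residue(
            "ASP", [("CG", "C", (0, 0, 0)), ("OD1", "O", (1.1, 0.6, 0)), ("OD2", "O", (1.1, -0.6, 0))]
        )
        s = assemble(chains={"A": [asp]})
        v = variant_of(assign_microstates(s), asp)
        assert v.code == "ASP-" and v.formal_charge == -1

    def test_arginine_neutralized_next_to_metal_cation(self):
        arg_near = make_arginine_head(number=1, origin=(0, 0, 0))
        arg_far = make_arginine_head(number=2, origin=(30, 0, 0))
        ni = make_nickel(position=(-2.0, 3.5, 0.0))  # ~4 A from NE/CZ group
        s = assemble(chains={"A": [arg_near, arg_far]}, metals=[ni])
        variants = assign_microstates(s)
        assert variant_of(variants, arg_near).code == "ARN"
        assert variant_of(variants, arg_near).formal_charge == 0
        assert variant_of(variants, arg_far).code == "ARG+"

    def test_metal_ligating_cysteine_is_thiolate(self):
        cys = make_residue("CYS", [("CB", "C", (0, 0, 0)), ("SG", "S", (1.8, 0, 0))])
        ni = make_nickel(position=(4.0, 0, 0))  # SG-Ni 2.2 A
        s = assemble(chains={"A": [cys]}, metals=[ni])
        v = variant_of(assign_microstates(s), cys)
        assert v.code == "CYS-" and v.formal_charge == -1 and v.constrained

    def test_histidine_with_anionic_oxygen_on_both_sides_is_hip(self):
        his = make_histidine(number=1)
        nd1 = his.atom("ND1").coords
        ne2 = his.atom("NE2").coords
        # carboxylate oxygens 2.7 A outward from each ring nitrogen
        out_d = unit(nd1 - np.array([0, 0.0, 0.0]))
        out_e = unit(ne2 - np.array([0, 0.0, 0.0]))
        asp = make_residue(
            "ASP",
            [("CG", "C", tuple(nd1 + 3.9 * out_d)), ("OD1", "O", tuple(nd1 + 2.7 * out_d)),
             ("OD2", "O", tuple(nd1 + 4.5 * out_d))],
            number=2,
        )
        wat = make_water(101, tuple(ne2 + 2.7 * out_e))
        s = assemble(chains={"A": [his, asp]}, waters=[wat])
        v = variant_of(assign_microstates(s), his)
        assert v.code == "HIP" and v.formal_charge == +1

    def test_histidine_tautomer_follows_available_acceptor(self):
        his = make_histidine(number=1)
        ne2 = his.atom("NE2").coords
        out_e = unit(ne2)
        wat = make_water(101, tuple(ne2 + 2.8 * out_e))
        s = assemble(chains={"A": [his]}, waters=[wat])
        v = variant_of(assign_microstates(s), his)
        assert v.code == "HIE"  # acceptor reachable only from NE2

    def test_lone_histidine_defaults_to_neutral(self):
        his = make_histidine(number=1)
        s = assemble(chains={"A": [his]})
        v = variant_of(assign_microstates(s), his)
        assert v.code in ("HID", "HIE") and v.formal_charge == 0


class TestHydrogenConstruction:
    def test_water_geometry(self):
        wat = make_water(101, (0, 0, 0))
        s = assemble(waters=[wat])
        place_hydrogens(s, [])
        hs = wat.hydrogens()
        assert len(hs) == 2
        o = wat.atom("O")
        for h in hs:
            assert abs(h.distance_to(o) - 0.96) < 1e-6
        ang = angle_deg(hs[0].coords - o.coords, hs[1].coords - o.coords)
        assert abs(ang - 104.52) < 1e-6

    def test_histidine_variants_hydrogen_counts(self):
        for code, names in [("HID", {"HD1"}), ("HIE", {"HE2"}), ("HIP", {"HD1", "HE2"})]:
            his = make_histidine(number=1)
            s = assemble(chains={"A": [his]})
            from protonwire.protonation import ProtonationVariant

            place_hydrogens(s, [ProtonationVariant(his, code, 0)])
            ring_h = {h.name for h in his.hydrogens() if h.name in ("HD1", "HE2")}
            assert ring_h == names

    def test_ring_hydrogen_in_plane_along_external_bisector(self):
        his = make_histidine(number=1)
        s = assemble(chains={"A": [his]})
        from protonwire.protonation import ProtonationVariant

        place_hydrogens(s, [ProtonationVariant(his, "HID", 0)])
        hd1 = next(h for h in his.hydrogens() if h.name == "HD1")
        assert abs(hd1.coords[2]) < 1e-9  # ring is in the xy-plane
        nd1 = his.atom("ND1")
        # external bisector: H is further from the ring centroid than ND1
        centroid = np.mean(
            [his.atom(n).coords for n in ("CG", "ND1", "CE1", "NE2", "CD2")], axis=0
        )
        assert np.linalg.norm(hd1.coords - centroid) > np.linalg.norm(nd1.coords - centroid)

    def test_hydroxyl_points_at_lone_acceptor(self):
        """Rotor optimum: H within 10 degrees of the reachable acceptor direction."""
        ser = make_residue("SER", [("CB", "C", (1.43, 0, 0)), ("OG", "O", (0, 0, 0))])
        axis = np.array([-1.0, 0.0, 0.0])  # CB -> OG
        half = np.radians(180.0 - 109.47)
        direction = np.cos(half) * axis + np.sin(half) * np.array([0.0, 1.0, 0.0])
        wat = make_water(101, tuple(2.8 * direction))
        s = assemble(chains={"A": [ser]}, waters=[wat])
        protonate(s)
        hg = next(h for h in ser.hydrogens() if h.name == "HG")
        og = ser.atom("OG")
        ang = angle_deg(hg.coords - og.coords, wat.atom("O").coords - og.coords)
        assert ang < 10.0

    def test_heavy_atoms_untouched_and_deterministic(self, wire_factory):
        s1, _ = wire_factory(protonated=False, n_nodes=6, seed=5)
        before = {
            (a.parent.key, a.name): a.coords.copy()
            for a in s1.all_atoms()
        }
        protonate(s1)
        for a in s1.all_atoms():
            if not a.is_hydrogen:
                assert np.array_equal(a.coords, before[(a.parent.key, a.name)])
        s2, _ = wire_factory(protonated=False, n_nodes=6, seed=5)
        protonate(s2)
        c1 = np.array([a.coords for a in s1.all_atoms()])
        c2 = np.array([a.coords for a in s2.all_atoms()])
        assert np.array_equal(c1, c2)

    def test_truncated_side_chain_warns_and_skips(self):
        broken = make_residue("SER", [("CB", "C", (0, 0, 0))])  # no OG
        s = assemble(chains={"A": [broken]})
        with pytest.warns(UserWarning, match="missing heavy atoms"):
            place_hydrogens(s, [])
        assert all(h.name.startswith("H") for h in broken.hydrogens())


class TestWaterOrientation:
    def test_water_bridges_two_acceptors(self):
        """A water midway between two acceptors donates to both, tightly."""
        ang = np.radians(104.52)
        d1 = np.array([1.0, 0.0, 0.0])
        d2 = np.array([np.cos(ang), np.sin(ang), 0.0])
        wat = make_water(101, (0, 0, 0))
        acc1 = make_water(102, tuple(2.8 * d1))
        acc2 = make_water(103, tuple(2.8 * d2))
        s = assemble(waters=[wat, acc1, acc2])
        protonate(s)
        o = wat.atom("O")
        for target in (acc1, acc2):
            best = min(
                np.linalg.norm(h.coords - target.atom("O").coords)
                for h in wat.hydrogens()
            )
            assert best < 2.2

    def test_isolated_water_keeps_seeded_orientation(self):
        coords = []
        for _ in range(2):
            wat = make_water(101, (0, 0, 0))
            s = assemble(waters=[wat])
            cfg = ProtonationConfig(random_seed=42)
            place_hydrogens(s, [], config=cfg)
            orient_waters(s, cfg)
            coords.append(np.array([h.coords for h in wat.hydrogens()]))
        assert np.array_equal(coords[0], coords[1])

    def test_planted_chain_fully_linked_after_orientation(self, wire_factory):
        structure, truth = wire_factory(n_nodes=6, seed=7)
        from protonwire.hbond import HBondCriteria, detect_hbonds

        bonds = detect_hbonds(structure, HBondCriteria())
        strong = [b for b in bonds if b.is_strong]

        def node(atom):
            from protonwire.hbond import node_id_for_atom

            return node_id_for_atom(atom)

        linked = {frozenset((node(b.donor), node(b.acceptor))) for b in strong}
        wire = truth.wire_nodes
        for a, b in zip(wire[:-1], wire[1:]):
            assert frozenset((a, b)) in linked
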