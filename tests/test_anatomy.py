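"""Static anatomy: membrane frame, tilt, contacts, bonds, layers, span, kink."""

import numpy as np
import pytest

from fivetm import anatomy, synthetic
from fivetm.structure import default_segment_map

from conftest import random_rigid_transform


def rotated(model, seed):
    rot, trans = random_rigid_transform(np.random.default_rng(seed))
    return model.with_xyz(model.xyz @ rot.T + trans), rot


class TestMembraneFrame:
    def test_vertical_bundle_axis(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        assert abs(frame.z_axis[2]) > 0.999  # within ~2.5 degrees of vertical
        assert np.linalg.norm(frame.z_axis) == pytest.approx(1.0)

    def test_boundary_sign_convention(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        ca123 = toy_model.xyz[toy_model.mask(residues=[123], atom_names=["CA"])][0]
        ca274 = toy_model.xyz[toy_model.mask(residues=[274], atom_names=["CA"])][0]
        assert frame.z_of(ca123) > 0 > frame.z_of(ca274)

    def test_frame_equivariance_under_rotation(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        moved, rot = rotated(toy_model, seed=7)
        frame2 = anatomy.build_frame(moved, seg)
        assert np.abs(frame2.z_axis - rot @ frame.z_axis).max() < 1e-3

    def test_missing_boundary_reference_errors(self, toy_model, seg):
        trimmed = toy_model.subset(toy_model.res_seq != 123)
        with pytest.raises(ValueError, match="123"):
            anatomy.build_frame(trimmed, seg)


class TestEcdTilt:
    def test_on_axis_limit_is_90(self, seg):
        structure, _ = synthetic.make_toy_receptor(tilt_deg=90.0)
        frame = anatomy.build_frame(structure.first, seg)
        assert anatomy.ecd_tilt(structure.first, frame) == pytest.approx(90.0, abs=1e-9)

    def test_in_plane_limit_is_0(self, seg):
        structure, _ = synthetic.make_toy_receptor(tilt_deg=0.0)
        frame = anatomy.build_frame(structure.first, seg)
        assert anatomy.ecd_tilt(structure.first, frame) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("tilt", [20.0, 40.0, 62.0, 80.0])
    def test_recovers_planted_tilt_under_noise(self, tilt, seg):
        for seed in range(10):
            structure, _ = synthetic.make_toy_receptor(tilt_deg=tilt, jitter_sd=0.05, seed=seed)
            frame = anatomy.build_frame(structure.first, seg)
            assert anatomy.ecd_tilt(structure.first, frame) == pytest.approx(tilt, abs=1.0)

    def test_range_and_rotation_invariance(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        tilt = anatomy.ecd_tilt(toy_model, frame)
        assert 0.0 <= tilt <= 90.0
        moved, _ = rotated(toy_model, seed=11)
        frame2 = anatomy.build_frame(moved, seg)
        assert anatomy.ecd_tilt(moved, frame2) == pytest.approx(tilt, abs=1e-3)

    def test_missing_tip_residues_error(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        trimmed = toy_model.subset(toy_model.res_seq != 34)
        with pytest.raises(ValueError, match="34"):
            anatomy.ecd_tilt(trimmed, frame)


def brute_force_contacts(model, seg, target, cutoff):
    prot = model.heavy_protein()
    found = set()
    for i in range(prot.n_atoms):
        for j in range(i + 1, prot.n_atoms):
            si = seg.segment_of(int(prot.res_seq[i]))
            sj = seg.segment_of(int(prot.res_seq[j]))
            if si is None or sj is None or si == sj:
                continue
            if target not in (si, sj):
                continue
            if prot.chain[i] == prot.chain[j] and abs(int(prot.res_seq[i]) - int(prot.res_seq[j])) <= 1:
                continue
            if np.linalg.norm(prot.xyz[i] - prot.xyz[j]) <= cutoff:
                a = (str(prot.chain[i]), int(prot.res_seq[i]), str(prot.atom_name[i]))
                b = (str(prot.chain[j]), int(prot.res_seq[j]), str(prot.atom_name[j]))
                found.add(tuple(sorted((a, b))))
    return found


class TestSegmentContacts:
    def test_cutoff_boundary(self, seg):
        model, expected, cutoff = synthetic.make_contact_fixture()
        contacts = anatomy.segment_contacts(model, seg, cutoff=cutoff)
        got = {(c.atom_a[1], c.atom_b[1]) for c in contacts}
        got = {tuple(sorted(p)) for p in got}
        assert got == {tuple(sorted(p)) for p in expected}
        # the 3.49 A pair is inside, the 3.60 A pair outside
        assert (195, 230) in {tuple(sorted(p)) for p in got}
        assert (131, 195) not in got

    def test_matches_exhaustive_pair_scan(self, toy_model, seg):
        contacts = anatomy.segment_contacts(toy_model, seg, cutoff=3.5)
        got = {tuple(sorted((c.atom_a, c.atom_b))) for c in contacts}
        assert got == brute_force_contacts(toy_model, seg, "helix III", 3.5)

    def test_monotone_in_cutoff(self, toy_model, seg):
        sets = []
        for cutoff in (3.0, 3.5, 4.0, 4.5, 5.0):
            c = anatomy.segment_contacts(toy_model, seg, cutoff=cutoff)
            sets.append({tuple(sorted((x.atom_a, x.atom_b))) for x in c})
        for small, large in zip(sets, sets[1:]):
            assert small <= large

    def test_unknown_segment_errors(self, toy_model, seg):
        with pytest.raises(ValueError, match="unknown segment"):
            anatomy.segment_contacts(toy_model, seg, target="helix IX")


class TestHydrogenBonds:
    def test_planted_switch_residue_bonds(self, toy):
        structure, truth = toy
        bonds = anatomy.hydrogen_bonds(structure.first)
        by_pair = {(b.donor_atom[1], b.donor_atom[2], b.acceptor_atom[1], b.acceptor_atom[2]): b.distance for b in bonds}
        for key, planted in truth.hbonds.items():
            assert by_pair[key] == pytest.approx(planted, abs=1e-6)

    def test_beyond_cutoff_not_reported(self, seg):
        structure, _ = synthetic.make_toy_receptor(hbond_distances=(5.0, 5.5))
        bonds = anatomy.hydrogen_bonds(structure.first)
        assert not any(184 in (b.donor_atom[1], b.acceptor_atom[1]) for b in bonds)

    def test_distance_window_lower_bound(self, toy_model):
        bonds = anatomy.hydrogen_bonds(toy_model)
        assert all(2.2 <= b.distance <= 3.5 for b in bonds)


class TestSaltBridges:
    def test_planted_pair_detected(self, toy):
        structure, truth = toy
        found = anatomy.salt_bridges(structure.first)
        acid, base, dist = truth.saltbridge
        match = [(a, b, d) for a, b, d in found if a[1] == acid and b[1] == base]
        assert len(match) == 1
        assert match[0][2] == pytest.approx(dist, abs=1e-6)

    def test_beyond_cutoff_not_detected(self):
        structure, _ = synthetic.make_toy_receptor(saltbridge_distance=4.5)
        found = anatomy.salt_bridges(structure.first, cutoff=4.0)
        assert not any(a[1] == 183 for a, b, d in found)

    def test_matches_brute_force_over_pairs(self, toy_model):
        prot = toy_model.heavy_protein()
        acid_atoms = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
        base_atoms = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2")}
        expected = set()
        for i in range(prot.n_atoms):
            for j in range(prot.n_atoms):
                rn_i, rn_j = str(prot.res_name[i]), str(prot.res_name[j])
                if str(prot.atom_name[i]) not in acid_atoms.get(rn_i, ()):
                    continue
                if str(prot.atom_name[j]) not in base_atoms.get(rn_j, ()):
                    continue
                if np.linalg.norm(prot.xyz[i] - prot.xyz[j]) <= 4.0:
                    expected.add((int(prot.res_seq[i]), int(prot.res_seq[j])))
        got = {(a[1], b[1]) for a, b, _ in anatomy.salt_bridges(toy_model, cutoff=4.0)}
        assert got == expected


class TestPolarNetwork:
    def test_network_bonds_are_subset_of_general_hbonds(self, toy_model):
        with pytest.warns(UserWarning):
            bonds, _ = anatomy.ic_polar_network(toy_model)
        general = {
            (b.donor_atom, b.acceptor_atom)
            for b in anatomy.hydrogen_bonds(toy_model)
        }
        for b in bonds:
            assert (b.donor_atom, b.acceptor_atom) in general

    def test_distant_members_give_empty_network(self, toy_model):
        # pick residues whose side chains are far apart on the toy
        bonds, comps = anatomy.ic_polar_network(toy_model, members=(206, 227, 264))
        assert bonds == []
        assert all(len(c) == 1 for c in comps)


class TestHydrophobicLayers:
    def test_planted_top_layer_membership(self, toy, seg):
        structure, truth = toy
        frame = anatomy.build_frame(structure.first, seg)
        layers = anatomy.hydrophobic_layers(structure.first, frame, seg)
        layer1 = {r["res_seq"] for r in layers if r["layer"] == 1}
        assert layer1 >= truth.layers[1]

    def test_outward_side_chains_are_not_core_facing(self, seg):
        structure, _ = synthetic.make_toy_receptor(plant_top_layer=False, sidechains="out")
        frame = anatomy.build_frame(structure.first, seg)
        layers = anatomy.hydrophobic_layers(structure.first, frame, seg)
        assert sum(r["core_facing"] for r in layers) == 0

    def test_planted_tier_count(self, seg):
        structure, truth = synthetic.make_toy_receptor(extra_tiers=(2.0, -8.0))
        frame = anatomy.build_frame(structure.first, seg)
        layers = anatomy.hydrophobic_layers(structure.first, frame, seg)
        observed = {r["layer"] for r in layers if r["layer"] is not None}
        assert observed == set(truth.layers)


class TestSpanAndKink:
    def test_toy_span_matches_planted(self, toy, seg):
        structure, truth = toy
        frame = anatomy.build_frame(structure.first, seg)
        assert anatomy.helix_span(structure.first, frame) == pytest.approx(truth.span, abs=0.5)

    def test_span_rotation_invariance(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        span = anatomy.helix_span(toy_model, frame)
        moved, _ = rotated(toy_model, seed=5)
        frame2 = anatomy.build_frame(moved, seg)
        assert anatomy.helix_span(moved, frame2) == pytest.approx(span, abs=1e-6)

    def test_straight_helix_has_no_kink(self, toy_model, seg):
        assert anatomy.kink_angle(toy_model, seg, helix="helix I", pivot=131) < 2.0

    @pytest.mark.parametrize("planted", [15.0, 30.0, 50.0])
    def test_planted_kink_recovered(self, planted, seg):
        model, truth = synthetic.make_kinked_helix(kink_deg=planted)
        assert anatomy.kink_angle(model, seg, helix="helix I", pivot=131) == pytest.approx(
            truth, abs=0.5
        )

    def test_short_arm_errors(self, seg):
        model, _ = synthetic.make_kinked_helix(kink_deg=30.0, arm=8)
        with pytest.raises(ValueError, match="needs"):
            anatomy.kink_angle(model, seg, helix="helix I", pivot=137)


class TestRigidMotionInvariance:
    def test_all_scalars_invariant(self, toy_model, seg):
        frame = anatomy.build_frame(toy_model, seg)
        base = {
            "tilt": anatomy.ecd_tilt(toy_model, frame),
            "span": anatomy.helix_span(toy_model, frame),
            "kink": anatomy.kink_angle(toy_model, seg, pivot=131),
            "n_contacts": len(anatomy.segment_contacts(toy_model, seg)),
            "n_hbonds": len(anatomy.hydrogen_bonds(toy_model)),
        }
        for seed in (3, 4):
            moved, _ = rotated(toy_model, seed=seed)
            frame2 = anatomy.build_frame(moved, seg)
            assert anatomy.ecd_tilt(moved, frame2) == pytest.approx(base["tilt"], abs=1e-3)
            assert anatomy.helix_span(moved, frame2) == pytest.approx(base["span"], abs=1e-3)
            assert anatomy.kink_angle(moved, seg, pivot=131) == pytest.approx(base["kink"], abs=1e-3)
            assert len(anatomy.segment_contacts(moved, seg)) == base["n_contacts"]
            assert len(anatomy.hydrogen_bonds(moved)) == base["n_hbonds"]
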