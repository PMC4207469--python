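"""Contact rules, fractional interactions, RDFs, residue contacts."""

import itertools

import numpy as np
import pytest

import membranekit as mk
from membranekit.contacts import (
    ContactParameters,
    fractional_interactions,
    lateral_rdf,
    lipid_pair_contacts,
    residue_lipid_contacts,
)
from membranekit.geometry import minimum_image_distance
from tests.conftest import simple_leaflet_frame


def brute_force_pairs(frame, leaflet, cutoff, exclude=("CHOL",)):
    """All-pairs oracle: min linker-linker distance over explicit images."""
    sel = frame.select_molecules(leaflet=leaflet, exclude_species=exclude, lipids_only=True)
    out = {}
    for a, b in itertools.combinations(sel, 2):
        pa, _ = frame.bead_positions(np.array([a]), "linker")
        pb, _ = frame.bead_positions(np.array([b]), "linker")
        dmin = min(
            minimum_image_distance(x, y, frame.box, mode="xyz") for x in pa for y in pb
        )
        if dmin < cutoff:
            key = tuple(sorted((str(frame.species[a]), str(frame.species[b]))))
            out[key] = out.get(key, 0) + 1
    return out


class TestPairContacts:
    def test_multiple_bead_pairs_count_once(self):
        f = simple_leaflet_frame([(50, 50), (55, 50)], ["POPC", "POPE"], (100, 100))
        counts = lipid_pair_contacts(f, "outer")
        assert counts == {("POPC", "POPE"): 1}

    def test_cutoff_is_strict_less_than(self):
        f = simple_leaflet_frame([(50, 50), (61, 50)], ["POPC", "POPC"], (100, 100))
        assert lipid_pair_contacts(f, "outer") == {}  # exactly 11.0 A apart
        g = simple_leaflet_frame([(50, 50), (60.99, 50)], ["POPC", "POPC"], (100, 100))
        assert lipid_pair_contacts(g, "outer") == {("POPC", "POPC"): 1}

    def test_three_mutually_adjacent_lipids_give_three_pairs(self):
        f = simple_leaflet_frame([(50, 50), (55, 50), (52.5, 54)], ["POPC"] * 3, (100, 100))
        assert lipid_pair_contacts(f, "outer") == {("POPC", "POPC"): 3}

    def test_contacts_wrap_across_boundary(self):
        f = simple_leaflet_frame([(2, 50), (97, 50)], ["POPC", "GM3"], (100, 100))
        assert lipid_pair_contacts(f, "outer") == {("GM3", "POPC"): 1}

    def test_cholesterol_excluded_by_default(self):
        f = simple_leaflet_frame([(50, 50), (55, 50)], ["POPC", "CHOL"], (100, 100))
        assert lipid_pair_contacts(f, "outer") == {}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        f = mk.make_random_leaflet(
            {"POPC": 0.4, "GM3": 0.3, "POPE": 0.3}, n=40, apl=120.0, seed=seed
        )
        assert lipid_pair_contacts(f, "outer") == brute_force_pairs(f, "outer", 11.0)


class TestFractionalInteractions:
    def test_row_stochastic(self):
        frames = [
            mk.make_random_leaflet({"POPC": 0.5, "GM3": 0.5}, n=300, seed=i) for i in range(3)
        ]
        m = fractional_interactions(frames, "outer")
        assert np.allclose(m.fractions.sum(axis=1), 1.0, atol=1e-9)
        assert ((m.fractions >= 0) & (m.fractions <= 1)).all()

    def test_two_species_random_mixing_near_half(self):
        frames = [mk.make_random_leaflet({"POPC": 0.5, "POPE": 0.5}, n=800, seed=i) for i in range(10)]
        m = fractional_interactions(frames, "outer")
        assert np.allclose(m.fractions, 0.5, atol=0.03)

    def test_abundance_correction_is_composition_invariant(self):
        frames = [
            mk.make_random_leaflet({"POPC": 0.7, "GM3": 0.3}, n=800, seed=100 + i) for i in range(10)
        ]
        m = fractional_interactions(frames, "outer")
        assert np.allclose(m.fractions, 0.5, atol=0.04)

    def test_pure_cluster_gives_unit_self_fraction(self):
        # two well-separated single-species blobs: A only contacts A
        xy = [(10, 10), (14, 10), (12, 14)] + [(60, 60), (64, 60), (62, 64)]
        f = simple_leaflet_frame(xy, ["GM3"] * 3 + ["POPC"] * 3, (100, 100))
        m = fractional_interactions([f], "outer")
        assert m[("GM3", "GM3")] == pytest.approx(1.0)
        assert m[("POPC", "POPC")] == pytest.approx(1.0)

    def test_single_species_normalises_to_one(self):
        f = mk.make_random_leaflet({"POPC": 1.0}, n=200, seed=0)
        m = fractional_interactions([f], "outer")
        assert m.fractions.shape == (1, 1)
        assert m[("POPC", "POPC")] == pytest.approx(1.0)

    def test_window_and_stride_select_frames(self):
        frames = []
        for i in range(10):
            f = mk.make_random_leaflet({"POPC": 1.0}, n=50, seed=i, time=float(i))
            frames.append(f)
        traj = mk.Trajectory(frames)
        params = ContactParameters(window=(4.0, 9.0), stride=2.0)
        m = fractional_interactions(traj, "outer", params)
        assert m.n_frames == 3


class TestLateralRdf:
    def test_uniform_targets_give_unit_plateau(self):
        frames = [mk.make_random_leaflet({"POPC": 1.0}, n=1000, seed=i) for i in range(5)]
        center = np.array([[50.0, 50.0]])
        df = lateral_rdf(frames, center, "POPC", bin_width=2.0, r_max=100.0)
        plateau = df[(df.r_A > 15)].g
        assert plateau.mean() == pytest.approx(1.0, abs=0.05)

    def test_ring_of_targets_peaks_at_ring_radius(self):
        theta = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        xy = np.column_stack([50 + 20 * np.cos(theta), 50 + 20 * np.sin(theta)])
        f = simple_leaflet_frame(xy, ["GM3"] * 24, (100, 100))
        df = lateral_rdf([f], np.array([[50.0, 50.0]]), "GM3", bin_width=1.0, r_max=40.0)
        assert df.loc[df.g.idxmax(), "r_A"] == pytest.approx(20.0, abs=0.5)

    def test_r_max_beyond_half_box_rejected(self):
        f = simple_leaflet_frame([(1, 1)], ["POPC"], (100, 100))
        with pytest.raises(ValueError, match="half"):
            lateral_rdf([f], np.array([[0.0, 0.0]]), "POPC", r_max=60.0)


class TestResidueContacts:
    def _frame_with_protein_and_lipid(self, lipid_xy, box=(100, 100, 100)):
        f = mk.generate_template_bilayer(81, seed=0)
        g = mk.place_protein_grid(f, 1, 10.0, exclusion_radius=0.0)
        mols = [
            (
                str(g.species[i]),
                int(g.mol_ids[i]),
                str(g.leaflets[i]),
                g.mol_coords(i),
                list(g.mol_bead_names(i)),
                None if g.residue_ids is None else g.residue_ids[g.mol_start[i] : g.mol_start[i + 1]],
            )
            for i in range(g.n_molecules)
        ]
        return g, mols

    def test_persistent_contact_flagged(self):
        g, mols = self._frame_with_protein_and_lipid(None)
        sel = g.select_molecules(species="PROT")[0]
        res10_pos = g.mol_coords(sel)[9]
        frames = []
        for t in range(10):
            near = t < 6  # within 6 A in 6 of 10 frames
            lipid_pos = res10_pos + (np.array([5.0, 0, 0]) if near else np.array([30.0, 0, 0]))
            from membranekit.synth import _reduced_layout

            names, offs = _reduced_layout("PIP2")
            beads = offs + lipid_pos
            fr = mk.MembraneFrame.from_molecules(
                mols + [("PIP2", 99999, "inner", beads, names)], box=g.box, time=float(t)
            )
            frames.append(fr)
        sp = mk.get_species("PIP2")
        df = residue_lipid_contacts(frames, "PIP2", [sp.head_beads[-1]])
        row = df[df.residue == 10].iloc[0]
        assert row.persistence == pytest.approx(0.6)
        assert bool(row.persistent)
        far = df[df.residue == 24].iloc[0]
        assert far.mean_contacts <= row.mean_contacts

    def test_no_contacts_all_zero(self):
        g, mols = self._frame_with_protein_and_lipid(None)
        fr = mk.MembraneFrame.from_molecules(mols, box=g.box)
        sp = mk.get_species("POPC")
        df = residue_lipid_contacts([fr], "POPC", sp.head_beads)
        assert (df.mean_contacts >= 0).all()
        assert not df.persistent.any() or df.persistence.max() <= 1.0

    def test_empty_selector_rejected(self):
        g, mols = self._frame_with_protein_and_lipid(None)
        fr = mk.MembraneFrame.from_molecules(mols, box=g.box)
        with pytest.raises(ValueError, match="matches no"):
            residue_lipid_contacts([fr], "POPC", ["NOPE"])
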