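import numpy as np
import pytest

from pairsite.labeling import (
    ChainStructure,
    compute_sasa,
    delta_rsa_labels,
    map_to_parent,
    residue_rsa,
    MAX_ASA_TIEN,
)
from pairsite.synth import generate_toy_complex


def _single_atom_chain(chain_id="A", element="C", xyz=(0.0, 0.0, 0.0)):
    return ChainStructure(
        chain_id=chain_id,
        residue_names=["ALA"],
        residue_numbers=[1],
        atom_elements=[element],
        atom_residue_index=np.array([0]),
        atom_coords=np.array([xyz]),
    )


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        # a lone carbon: SASA = 4*pi*(1.7 + 1.4)^2
        sasa = compute_sasa([_single_atom_chain()])["A"]
        expected = 4 * np.pi * (1.7 + 1.4) ** 2
        assert sasa[0] == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(120.76, abs=0.01)

    def test_distant_atoms_additive(self):
        a = _single_atom_chain("A", xyz=(0, 0, 0))
        b = _single_atom_chain("B", xyz=(100, 0, 0))
        sasa = compute_sasa([a, b])
        single = 4 * np.pi * (1.7 + 1.4) ** 2
        assert sasa["A"][0] + sasa["B"][0] == pytest.approx(2 * single, rel=1e-3)

    @pytest.mark.parametrize("separation", [2.0, 3.0, 4.5])
    def test_two_overlapping_spheres_match_cap_formula(self, separation):
        # equal expanded spheres radius R at distance D occlude a cap of
        # fractional area (1 - D/(2R))/2 on each
        a = _single_atom_chain("A", xyz=(0, 0, 0))
        b = _single_atom_chain("B", xyz=(separation, 0, 0))
        R = 1.7 + 1.4
        frac_buried = (1 - separation / (2 * R)) / 2
        expected = 4 * np.pi * R**2 * (1 - frac_buried)
        sasa = compute_sasa([a, b], n_points=960)
        assert sasa["A"][0] == pytest.approx(expected, rel=0.02)

    def test_agrees_with_biotite_on_random_cluster(self):
        import biotite.structure as struc

        g = np.random.default_rng(0)
        n = 12
        coords = g.uniform(0, 8, size=(n, 3))
        chain = ChainStructure(
            chain_id="A",
            residue_names=["ALA"] * n,
            residue_numbers=list(range(1, n + 1)),
            atom_elements=["C"] * n,
            atom_residue_index=np.arange(n),
            atom_coords=coords,
        )
        ours = compute_sasa([chain], n_points=960)["A"]

        arr = struc.AtomArray(n)
        arr.coord = coords.astype(np.float32)
        arr.chain_id[:] = "A"
        arr.res_id[:] = np.arange(1, n + 1)
        arr.res_name[:] = "ALA"
        arr.atom_name[:] = "CA"
        arr.element[:] = "C"
        theirs = struc.sasa(arr, probe_radius=1.4, point_number=960,
                            vdw_radii=np.full(n, 1.7))
        np.testing.assert_allclose(ours, theirs, rtol=0.03)

    def test_empty_structure_rejected(self):
        chain = ChainStructure("A", [], [], [], np.array([], dtype=int),
                               np.zeros((0, 3)))
        with pytest.raises(ValueError):
            compute_sasa([chain])


class TestRsa:
    def test_ratio_to_max_asa(self):
        rsa = residue_rsa(np.array([54.5]), ["ALA"], {"ALA": 109.0})
        assert rsa[0] == pytest.approx(50.0)

    def test_extremes(self):
        rsa = residue_rsa(np.array([0.0, MAX_ASA_TIEN["GLY"]]), ["ALA", "GLY"])
        assert rsa[0] == 0.0
        assert rsa[1] == pytest.approx(100.0)

    def test_unknown_type_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="maxASA"):
            rsa = residue_rsa(np.array([100.0]), ["XYZ"])
        assert rsa[0] == pytest.approx(100.0 * 100.0 / 200.0)


class TestDeltaRsaLabels:
    def test_single_chain_self_complex_all_zero(self):
        a, _ = generate_toy_complex(6, 1, set(), seed=0)
        labels = delta_rsa_labels([a], focal_chain="A")
        assert labels.sum() == 0

    def test_toy_contact_labels_exact(self):
        a, b = generate_toy_complex(8, 3, {2, 5}, seed=0)
        labels = delta_rsa_labels([a, b], focal_chain="A")
        np.testing.assert_array_equal(np.flatnonzero(labels), [2, 5])

    def test_threshold_is_strict(self):
        a, b = generate_toy_complex(6, 1, {3}, seed=0)
        # measure the actual ΔRSA at the contact, then use it as threshold:
        # strict '>' means the label must vanish
        from pairsite.labeling import compute_sasa, residue_rsa

        rsa_iso = residue_rsa(compute_sasa([a])["A"], a.residue_names)
        rsa_cpx = residue_rsa(compute_sasa([a, b])["A"], a.residue_names)
        delta = (rsa_iso - rsa_cpx)[3]
        assert delta > 4.0
        labels = delta_rsa_labels([a, b], focal_chain="A", threshold=float(delta))
        assert labels[3] == 0

    def test_separation_monotonicity(self):
        a, b = generate_toy_complex(10, 4, {1, 4, 7}, seed=1)
        rsa_iso = residue_rsa(compute_sasa([a])["A"], a.residue_names)
        rsa_cpx = residue_rsa(compute_sasa([a, b])["A"], a.residue_names)
        assert np.all(rsa_iso - rsa_cpx >= -1e-9)

    def test_distant_chains_additive_sasa(self):
        a, b = generate_toy_complex(5, 2, set(), seed=2)  # B placed >= 50 A away
        together = compute_sasa([a, b])
        apart_a = compute_sasa([a])["A"]
        apart_b = compute_sasa([b])["B"]
        np.testing.assert_allclose(together["A"], apart_a, rtol=1e-6)
        np.testing.assert_allclose(together["B"], apart_b, rtol=1e-6)


class TestMapToParent:
    def test_identical_sequences_copy_labels(self):
        labels = np.array([0, 1, 0, 1, 0])
        track = map_to_parent(labels, "MKVLA", "MKVLA", parent_id="P1")
        np.testing.assert_array_equal(track.labels, labels)
        assert track.coverage_mask.all()

    def test_n_terminal_extension_shifts_labels(self):
        labels = np.array([0, 1, 0, 0, 1])
        structure = "MKVLA"
        parent = "GGGGG" + structure
        track = map_to_parent(labels, structure, parent)
        np.testing.assert_array_equal(np.flatnonzero(track.labels), [6, 9])
        assert track.coverage_mask[:5].sum() == 0

    def test_low_identity_mapping_rejected(self):
        with pytest.raises(ValueError, match="identity"):
            map_to_parent(np.zeros(6, dtype=int), "MKVLAW", "PPPPPP")

    def test_label_at_gap_dropped_with_warning(self):
        # structural insertion absent from the parent carries a label
        structure = "MKVWWWLA"
        parent = "MKVLA"
        labels = np.zeros(8, dtype=int)
        labels[4] = 1  # inside the WWW insertion
        with pytest.warns(UserWarning, match="dropped"):
            track = map_to_parent(labels, structure, parent, min_identity_pct=50)
        assert track.labels.sum() == 0
        assert track.n_dropped_labels == 1
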