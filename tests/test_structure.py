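"""Structure descriptors: parsing, shells, secondary structure,
exposure, depth and contact-network metrics."""

import numpy as np
import pytest

from omegafeat import structure as st
from omegafeat.fixtures import build_peptide, peptide_to_pdb, toy_structure_pdb
from omegafeat.structure import (
    Residue,
    ShellScheme,
    StructureModel,
    assign_secondary_structure,
    atom_shell_composition,
    half_sphere_exposure,
    network_indices,
    parse_structure,
    residue_depth,
    shell_residue_composition,
)


def point_residue(key_num, name, xyz, chain="A"):
    """Minimal one-atom residue (Calpha only) for geometric tests."""
    r = Residue(chain, key_num, " ", name)
    r.atoms["CA"] = ("C", np.asarray(xyz, dtype=float))
    return r


def point_model(coords, names=None):
    names = names or ["ALA"] * len(coords)
    return StructureModel(
        [point_residue(i + 1, n, c) for i, (n, c) in enumerate(zip(names, coords))]
    )


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


class TestParsing:
    def test_toy_fixture_residue_count(self):
        model = parse_structure(toy_structure_pdb())
        assert len(model) == 16

    def test_two_model_file_keeps_first_model(self):
        body = peptide_to_pdb(build_peptide("AAAA"))
        core = "\n".join(
            l for l in body.splitlines() if l.startswith("ATOM")
        )
        text = f"MODEL     1\n{core}\nENDMDL\nMODEL     2\n{core}\nENDMDL\nEND\n"
        model = parse_structure(text)
        assert len(model) == 4

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            parse_structure("END\n")

    def test_glycine_cb_synthesized_and_flagged(self):
        model = parse_structure(peptide_to_pdb(build_peptide("AGA")))
        gly = model.residues[1]
        assert gly.name == "GLY" and "CB" in gly.atoms and gly.cb_synthesized

    def test_altloc_resolved_to_highest_occupancy(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C\n"
            "END\n"
        )
        model = parse_structure(text)
        assert model.residues[0].ca[0] == pytest.approx(5.0)


class TestShells:
    def test_single_neighbour_hand_geometry(self):
        model = point_model([[0, 0, 0], [5, 0, 0]], ["GLY", "ALA"])
        fm = shell_residue_composition(
            model, targets=["A1"], scheme=ShellScheme(0, 10, 1), mode="type1"
        )
        assert fm.values[0][fm.feature_names.index("AAC_type1.s1.A")] == 1.0
        assert fm.values[0].sum() == 1.0  # only the ALA neighbour counted

    def test_half_open_boundary_falls_in_next_shell(self):
        # neighbour at exactly r0 + delta belongs to shell 2
        model = point_model([[0, 0, 0], [4.0, 0, 0]])
        fm = shell_residue_composition(
            model, targets=["A1"], scheme=ShellScheme(0, 4.0, 2)
        )
        names = fm.feature_names
        assert fm.values[0][names.index("AAC_type1.s1.A")] == 0.0
        assert fm.values[0][names.index("AAC_type1.s2.A")] == 1.0

    def test_cumulative_counts_monotone(self, toy_model):
        scheme = ShellScheme(0, 2.0, 8)
        for label, site, exclude in st.resolve_targets(toy_model, None):
            counts = st._shell_category_counts(
                toy_model, site, exclude, scheme, list("ACDEFGHIKLMNPQRSTVWY"),
                [r.one_letter for r in toy_model.residues],
            )
            cum = np.cumsum(counts, axis=0)
            assert (np.diff(cum, axis=0) >= 0).all()

    def test_type1_blocks_sum_to_one_or_zero(self, toy_model):
        fm = shell_residue_composition(toy_model, mode="type1")
        vals = fm.values.reshape(fm.shape[0], -1, 20)
        sums = vals.sum(axis=2)
        assert np.all(
            (np.abs(sums - 1) < 1e-9) | (np.abs(sums) < 1e-12)
        )

    def test_matches_brute_force_distance_filtering(self, toy_model):
        scheme = ShellScheme(0, 3.0, 6)
        fm = atom_shell_composition(toy_model, scheme=scheme, mode="type1")
        # brute force for the first residue target
        target = toy_model.residues[0].ca
        atoms = [
            (xyz, el if el in ("C", "N", "O", "S") else "other")
            for r in toy_model.residues
            for _, (el, xyz) in r.atoms.items()
            if el != "H"
        ]
        expect = np.zeros((6, 5))
        for xyz, t in atoms:
            d = np.linalg.norm(xyz - target)
            if d == 0:
                continue
            s = int(d // 3.0)
            if s < 6:
                expect[s, st.ATOM_TYPES.index(t)] += 1
        sums = expect.sum(axis=1, keepdims=True)
        freqs = np.divide(expect, sums, out=np.zeros_like(expect),
                          where=sums > 0)
        assert np.allclose(fm.values[0], freqs.ravel(), atol=1e-9)

    def test_unknown_target_rejected(self, toy_model):
        with pytest.raises(ValueError, match="not in model"):
            shell_residue_composition(toy_model, targets=["Z99"])


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_helical(self, helix_model):
        eight, three = assign_secondary_structure(helix_model)
        interior = eight[4:-4]
        assert all(s == "H" for s in interior)
        assert all(t == "H" for t in three[4:-4])

    def test_extended_chain_has_no_helix(self, extended_model):
        eight, _ = assign_secondary_structure(extended_model)
        assert "H" not in eight and "G" not in eight and "I" not in eight

    def test_three_state_collapse_mapping(self, helix_model):
        eight, three = assign_secondary_structure(helix_model)
        for e, t in zip(eight, three):
            if e in "HGI":
                assert t == "H"
            elif e in "EB":
                assert t == "E"
            else:
                assert t == "C"

    def test_ss3_type2_equals_collapsed_ss8_type2(self, toy_model):
        scheme = ShellScheme(0, 2.0, 10)
        fm3 = st.ss_shell_composition(toy_model, scheme=scheme, states=3,
                                      mode="type2")
        fm8 = st.ss_shell_composition(toy_model, scheme=scheme, states=8,
                                      mode="type2")
        collapse = {"H": "H", "G": "H", "I": "H", "E": "E", "B": "E",
                    "T": "C", "S": "C", "-": "C"}
        v8 = fm8.values.reshape(fm8.shape[0], 10, 8)
        merged = np.zeros((fm8.shape[0], 10, 3))
        for j, s in enumerate(st.SS8_STATES):
            k = st.SS3_STATES.index(collapse[s])
            merged[:, :, k] += v8[:, :, j]
        assert np.allclose(
            fm3.values, merged.reshape(fm3.shape[0], -1), atol=1e-9
        )

    def test_all_helix_fixture_full_helix_frequency(self, helix_model):
        # restrict to a shell range the helix interior fills
        fm = st.ss_shell_composition(
            helix_model, targets=["A10"], scheme=ShellScheme(0, 6, 1),
            states=3, mode="type1",
        )
        names = fm.feature_names
        h = fm.values[0][names.index("SS3_type1.s1.H")]
        assert h == 1.0


class TestHalfSphereExposure:
    def test_dot_product_geometry(self):
        # side chain along +z; one neighbour above, one below, one outside
        target = Residue("A", 1, " ", "ALA")
        target.atoms["CA"] = ("C", np.zeros(3))
        target.atoms["CB"] = ("C", np.array([0.0, 0.0, 1.5]))
        up = point_residue(2, "ALA", [0, 0, 5])
        down = point_residue(3, "ALA", [0, 0, -5])
        far = point_residue(4, "ALA", [0, 0, 20])
        model = StructureModel([target, up, down, far])
        fm = half_sphere_exposure(model, variant="CB")
        assert list(fm.values[0]) == [1.0, 1.0]  # 20 A neighbour excluded

    def test_partition_identity(self, toy_model):
        fm = half_sphere_exposure(toy_model, variant="CB")
        cas = np.array([r.ca for r in toy_model.residues])
        for i, row in enumerate(fm.values):
            d = np.linalg.norm(cas - cas[i], axis=1)
            n_neigh = int(((d <= 13.0) & (d > 0)).sum())
            assert row[0] + row[1] == n_neigh

    def test_pseudo_cb_variant_runs_on_glycine_only_chain(self):
        model = parse_structure(peptide_to_pdb(build_peptide("GGGGG")))
        fm = half_sphere_exposure(model, variant="PseudoCB")
        assert fm.shape == (5, 2)


class TestResidueDepth:
    def test_isolated_atom_depth_zero(self):
        model = point_model([[0, 0, 0]])
        fm = residue_depth(model, n_points=240)
        assert fm.values[0][0] == pytest.approx(0.0, abs=1e-9)

    def test_lattice_center_deeper_than_corner(self):
        coords = [
            [3.0 * i, 3.0 * j, 3.0 * k]
            for i in range(3) for j in range(3) for k in range(3)
        ]
        model = point_model(coords)
        fm = residue_depth(model, n_points=240)
        center = fm.values[13][0]  # (1,1,1) position in the 3x3x3 lattice
        corner = fm.values[0][0]
        assert center > corner

    def test_sampling_convergence(self, toy_model):
        a = residue_depth(toy_model, n_points=480).values
        b = residue_depth(toy_model, n_points=960).values
        assert np.abs(a - b).max() < 0.2


class TestNetworkIndices:
    def test_collinear_chain_metrics(self):
        model = point_model([[0, 0, 0], [5, 0, 0], [10, 0, 0]])
        fm = network_indices(model, cutoff=8.0)
        names = fm.feature_names
        deg = fm.values[:, names.index("NetworkIndex.degree")]
        assert list(deg) == [1.0, 2.0, 1.0]
        btw = fm.values[:, names.index("NetworkIndex.betweenness")]
        assert btw[1] == pytest.approx(1.0)

    def test_triangle_clustering_coefficient(self):
        model = point_model([[0, 0, 0], [5, 0, 0], [2.5, 4, 0]])
        fm = network_indices(model, cutoff=8.0)
        clus = fm.values[:, fm.feature_names.index(
            "NetworkIndex.clustering_coefficient")]
        assert np.allclose(clus, 1.0)

    def test_single_residue_all_zero(self):
        model = point_model([[0, 0, 0]])
        fm = network_indices(model)
        assert np.allclose(fm.values, 0.0)

    def test_matches_bfs_oracle_on_random_structures(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = 12
            coords = rng.uniform(0, 15, size=(n, 3))
            model = point_model(coords.tolist())
            fm = network_indices(model, cutoff=8.0)
            adj = np.zeros((n, n), dtype=bool)
            for i in range(n):
                for j in range(n):
                    if i != j and np.linalg.norm(coords[i] - coords[j]) <= 8:
                        adj[i, j] = True
            names = fm.feature_names
            deg = adj.sum(axis=1)
            assert np.allclose(
                fm.values[:, names.index("NetworkIndex.degree")], deg
            )
            if deg.sum() == 0:
                continue
            assert np.allclose(
                fm.values[:, names.index("NetworkIndex.degree_centrality")],
                deg / (n - 1), atol=1e-9,
            )
            # closeness via BFS (Wasserman-Faust per-component scaling)
            for i in range(n):
                dist = np.full(n, -1)
                dist[i] = 0
                frontier = [i]
                while frontier:
                    nxt = []
                    for u in frontier:
                        for v in np.nonzero(adj[u])[0]:
                            if dist[v] == -1:
                                dist[v] = dist[u] + 1
                                nxt.append(v)
                    frontier = nxt
                reach = dist > 0
                total = dist[reach].sum()
                if total > 0:
                    expect = (reach.sum() / total) * (reach.sum() / (n - 1))
                else:
                    expect = 0.0
                assert fm.values[i, names.index("NetworkIndex.closeness")] == (
                    pytest.approx(expect, abs=1e-9)
                )


class TestRigidMotionInvariance:
    @pytest.mark.parametrize(
        "descriptor",
        [d for d in st.STRUCTURE_DESCRIPTORS if d != "ResidueDepth"],
    )
    def test_exact_invariance(self, toy_model, descriptor):
        rng = np.random.default_rng(42)
        rot = random_rotation(rng)
        shift = rng.uniform(-20, 20, size=3)
        moved = toy_model.transformed(rot, shift)
        a = st.compute(toy_model, descriptor)
        b = st.compute(moved, descriptor)
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_depth_invariance_within_sampling_tolerance(self, toy_model):
        # fixed-orientation sphere sampling limits depth equivariance to
        # the sampling resolution
        rng = np.random.default_rng(43)
        rot = random_rotation(rng)
        moved = toy_model.transformed(rot, np.array([3.0, -7.0, 11.0]))
        a = residue_depth(toy_model).values
        b = residue_depth(moved).values
        assert np.abs(a - b).max() < 0.1
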