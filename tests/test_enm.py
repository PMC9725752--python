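"""Elastic network construction, inversion and structure/covariance I/O."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from icdc import enm, fixtures, response
from icdc.enm import ResidueKey, build_hessian, invert_kernel, load_covariance, pseudoinverse

from conftest import square_hessian_oracle


PDB_3RES = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       4.800   0.100   0.000  1.00  0.00           C
ATOM      4  CA  SER A   3       8.600   0.000   0.300  1.00  0.00           C
END
"""

PDB_2MODEL = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       0.000   0.000   1.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   1.000  1.00  0.00           C
ENDMDL
END
"""

PDB_MISSING_CA = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  N   GLY A   2       3.800   0.000   0.000  1.00  0.00           N
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


class TestReadStructure:
    def test_single_model(self, tmp_path):
        path = tmp_path / "three.pdb"
        path.write_text(PDB_3RES)
        s = enm.read_structure(path)
        assert s.n_residues == 3
        assert s.n_models == 1
        assert [r.key for r in s.residues] == [
            ResidueKey("A", 1), ResidueKey("A", 2), ResidueKey("A", 3)
        ]
        assert np.allclose(s.coords()[0], [1.0, 0.0, 0.0])

    def test_model_policy_all(self, tmp_path):
        path = tmp_path / "two_models.pdb"
        path.write_text(PDB_2MODEL)
        s = enm.read_structure(path, model_policy="all")
        assert s.n_models == 2
        assert s.n_residues == 2
        np.testing.assert_allclose(s.models[1].ca[:, 2], 1.0)
        first_only = enm.read_structure(path, model_policy="first")
        assert first_only.n_models == 1

    def test_residue_without_calpha_dropped(self, tmp_path, caplog):
        path = tmp_path / "gap.pdb"
        path.write_text(PDB_MISSING_CA)
        with caplog.at_level("WARNING", logger="icdc.enm"):
            s = enm.read_structure(path)
        assert s.n_residues == 2
        assert any("dropped" in rec.message for rec in caplog.records)

    def test_roundtrip_through_writer(self, tmp_path, dumbbell):
        path = tmp_path / "dumbbell.pdb"
        fixtures.write_pdb(dumbbell, path)
        back = enm.read_structure(path)
        assert back.n_residues == dumbbell.n_residues
        # PDB coordinate fields carry 3 decimals
        np.testing.assert_allclose(back.coords(), dumbbell.coords(), atol=1e-3)


class TestBuildHessian:
    def test_single_spring_spectrum(self):
        s = fixtures.make_chain(2, noise=0.0)
        h = build_hessian(s, cutoff=5.0, spring_constant=1.0)
        w = np.sort(np.linalg.eigvalsh(h.matrix))
        np.testing.assert_allclose(w[:5], 0.0, atol=1e-12)
        np.testing.assert_allclose(w[5], 2.0, atol=1e-12)

    def test_no_contact_gives_zero_matrix(self):
        s = fixtures.make_chain(2, noise=0.0)
        h = build_hessian(s, cutoff=1.0)
        assert np.all(h.matrix == 0.0)

    def test_square_spectrum_matches_oracle(self, square):
        h = build_hessian(square, cutoff=1.5, spring_constant=1.0)
        oracle = square_hessian_oracle(square.coords(), cutoff=1.5, gamma=1.0)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(h.matrix), np.linalg.eigvalsh(oracle), atol=1e-10
        )

    def test_invariants_on_dumbbell(self, dumbbell):
        h = build_hessian(dumbbell)
        m = h.matrix
        assert np.abs(m - m.T).max() <= 1e-8 * np.abs(m).max()
        n = h.n_residues
        rows = m.reshape(3 * n, n, 3).sum(axis=1)
        np.testing.assert_allclose(rows, 0.0, atol=1e-8)
        w = np.linalg.eigvalsh(m)
        assert w.min() >= -1e-8
        assert int(np.sum(np.abs(w) < 1e-6 * w.max())) == 6

    def test_translation_invariance(self, dumbbell):
        """Only pairwise differences enter; a rigid shift changes nothing but
        the rounding of the coordinates themselves."""
        h1 = build_hessian(dumbbell).matrix
        shifted = fixtures.make_dumbbell(8, seed=0)
        for model in shifted.models:
            model.ca = model.ca + np.array([11.0, -3.0, 7.0])
        h2 = build_hessian(shifted).matrix
        np.testing.assert_allclose(h2, h1, atol=1e-12)

    def test_rotation_equivariance(self, square):
        rot = special_ortho_group.rvs(3, random_state=5)
        h = build_hessian(square, cutoff=1.5)
        rotated = fixtures.make_square()
        for model in rotated.models:
            model.ca = model.ca @ rot.T
        h_rot = build_hessian(rotated, cutoff=1.5)
        n = square.n_residues
        for i in range(n):
            for j in range(n):
                b = h.matrix[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
                b_rot = h_rot.matrix[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]
                np.testing.assert_allclose(b_rot, rot @ b @ rot.T, atol=1e-12)
        np.testing.assert_allclose(
            np.linalg.eigvalsh(h.matrix), np.linalg.eigvalsh(h_rot.matrix), atol=1e-9
        )

    def test_coincident_atoms_rejected(self):
        s = fixtures.make_chain(3, noise=0.0)
        s.models[0].ca[1] = s.models[0].ca[0]
        with pytest.raises(ValueError, match="coincident"):
            build_hessian(s)


class TestInvertKernel:
    def test_two_site_closed_form(self):
        h = np.array([[1.0, -1.0], [-1.0, 1.0]])
        np.testing.assert_allclose(
            pseudoinverse(h, null_modes=1), 0.25 * h, atol=1e-12
        )

    def test_pseudoinverse_identity_on_square(self, square):
        h = build_hessian(square, cutoff=1.5).matrix
        k = pseudoinverse(h, null_modes=None)
        np.testing.assert_allclose(k @ h @ k, k, atol=1e-8)
        np.testing.assert_allclose(h @ k @ h, h, atol=1e-8)

    def test_matches_eigendecomposition_oracle(self, square):
        h = build_hessian(square, cutoff=1.5).matrix
        w, v = np.linalg.eigh(h)
        keep = np.abs(w) > 1e-9 * np.abs(w).max()
        oracle = sum(np.outer(v[:, i], v[:, i]) / w[i] for i in np.flatnonzero(keep))
        np.testing.assert_allclose(pseudoinverse(h, null_modes=None), oracle, atol=1e-10)

    def test_projector_property(self, dumbbell):
        h = build_hessian(dumbbell)
        k = invert_kernel(h, null_modes=6)
        product = k.matrix @ h.matrix
        # product must be the orthogonal projector onto the retained eigenspace
        np.testing.assert_allclose(product @ product, product, atol=1e-8)
        assert abs(np.trace(product) - (3 * h.n_residues - 6)) < 1e-6

    def test_near_singular_retained_mode_is_error(self, square):
        h = build_hessian(square, cutoff=1.5)
        with pytest.raises(ValueError, match="near-singular"):
            invert_kernel(h, null_modes=6)  # planar: more than 6 null modes

    def test_minimum_norm_solve_oracle(self, dumbbell):
        """Kernel responses equal per-force minimum-norm least-squares solves."""
        h = build_hessian(dumbbell)
        k = invert_kernel(h)
        rng = np.random.default_rng(3)
        for _ in range(5):
            f = rng.normal(size=h.matrix.shape[0])
            x_kernel = k.matrix @ f
            x_lstsq, *_ = np.linalg.lstsq(h.matrix, f, rcond=None)
            np.testing.assert_allclose(x_kernel, x_lstsq, atol=1e-8)


class TestCovarianceIO:
    def test_identity_roundtrip(self, tmp_path):
        path = tmp_path / "cov.mat"
        path.write_text("\n".join(" ".join("1" if i == j else "0" for j in range(6)) for i in range(6)))
        kernel = load_covariance(path, n_residues=2)
        np.testing.assert_allclose(kernel.matrix, np.eye(6))
        assert kernel.source == "supplied-covariance"

    def test_wrong_dimension_reports_expected_size(self, tmp_path):
        path = tmp_path / "bad.mat"
        path.write_text("\n".join(" ".join("1" for _ in range(5)) for _ in range(5)))
        with pytest.raises(ValueError, match="6x6"):
            load_covariance(path, n_residues=2)

    def test_asymmetry_rejected(self, tmp_path):
        m = np.eye(6)
        m[0, 1] = 0.5
        path = tmp_path / "asym.mat"
        np.savetxt(path, m)
        with pytest.raises(ValueError, match="asymmetric"):
            load_covariance(path, n_residues=2)

    def test_comma_delimited_and_comments(self, tmp_path):
        path = tmp_path / "csvish.mat"
        path.write_text("# header\n1,0\n0,2\n")
        from icdc.io import load_matrix
        np.testing.assert_allclose(load_matrix(path), [[1, 0], [0, 2]])

    def test_kernel_source_equivalence(self, tmp_path, dumbbell, dumbbell_kernel):
        """DFI from the in-memory kernel and from a disk round-trip agree to 1e-12."""
        path = tmp_path / "kernel.mat"
        enm.save_kernel(dumbbell_kernel, path)
        reloaded = load_covariance(path, n_residues=dumbbell.n_residues)
        dfi_mem = response.compute_dfi(response.scan_responses(dumbbell_kernel)).dfi
        dfi_disk = response.compute_dfi(response.scan_responses(reloaded)).dfi
        np.testing.assert_allclose(dfi_mem, dfi_disk, atol=1e-12)
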