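"""Strain differentiation, principal strains, von Mises, node masking."""

import numpy as np
import pytest

from trabdvc import (
    BinaryMask,
    build_grid,
    differentiate,
    mask_nodes,
    principal_strains,
    von_mises,
)
from trabdvc.dvc_core import DisplacementField, node_mask_coverage
from trabdvc.strainfield import COMPONENTS, load_strain, save_strain


def field_from_gradient(A, dims=(64, 64, 64), ns=16, voxel_size=39.0):
    """DisplacementField with exact nodal u = A x (voxel units)."""
    grid = build_grid(dims, voxel_size, ns)
    pos = grid.node_positions()
    u_vox = pos @ np.asarray(A, dtype=float).T
    return DisplacementField(
        grid=grid,
        u=u_vox * voxel_size,
        converged=True,
        residual=0.0,
        smoothing_weight=0.0,
    )


class TestDifferentiate:
    def test_uniaxial_gradient(self):
        A = np.zeros((3, 3))
        A[2, 2] = -0.01
        strain = differentiate(field_from_gradient(A))
        np.testing.assert_allclose(strain.eps[..., 2], -10_000.0, rtol=1e-9)
        for i in (0, 1, 3, 4, 5):
            np.testing.assert_allclose(strain.eps[..., i], 0.0, atol=1e-9)

    def test_pure_shear(self):
        c = 0.004
        A = np.zeros((3, 3))
        A[0, 1] = c
        A[1, 0] = c
        strain = differentiate(field_from_gradient(A))
        np.testing.assert_allclose(strain.eps[..., 3], c * 1e6, rtol=1e-9)
        for i in (0, 1, 2):
            np.testing.assert_allclose(strain.eps[..., i], 0.0, atol=1e-6)
        np.testing.assert_allclose(
            strain.engineering_shears()[..., 0], 2 * c * 1e6, rtol=1e-9
        )

    def test_random_linear_field_matches_central_difference_oracle(self):
        rng = np.random.default_rng(7)
        A = 0.01 * rng.standard_normal((3, 3))
        dfield = field_from_gradient(A)
        strain = differentiate(dfield)
        # oracle: central differences of the nodal displacement arrays
        u = dfield.u_voxels
        ns = dfield.grid.ns
        G = np.empty((3, 3))
        for i in range(3):
            for j in range(3):
                G[i, j] = np.gradient(u[..., i], ns, axis=j)[2, 2, 2]
        sym = 0.5 * (G + G.T) * 1e6
        expected = np.array(
            [sym[0, 0], sym[1, 1], sym[2, 2], sym[0, 1], sym[1, 2], sym[0, 2]]
        )
        np.testing.assert_allclose(strain.eps[2, 2, 2], expected, rtol=1e-9)
        # and equals sym(A) at every node for an exactly linear field
        np.testing.assert_allclose(
            strain.eps.reshape(-1, 6) - expected, 0.0, atol=1e-6
        )

    def test_trace_identity_every_node(self):
        rng = np.random.default_rng(8)
        A = 0.01 * rng.standard_normal((3, 3))
        strain = differentiate(field_from_gradient(A))
        trace_cart = strain.eps[..., :3].sum(axis=-1)
        trace_princ = strain.principal.sum(axis=-1)
        np.testing.assert_allclose(trace_cart, trace_princ, rtol=1e-6)

    def test_rigid_translation_is_strain_free(self):
        grid = build_grid((64, 64, 64), 39.0, 16)
        u = np.broadcast_to(
            np.array([3.0, -2.0, 5.0]) * 39.0, grid.shape + (3,)
        ).copy()
        field = DisplacementField(
            grid=grid, u=u, converged=True, residual=0.0, smoothing_weight=0.0
        )
        strain = differentiate(field)
        assert np.abs(strain.eps).max() <= 10.0


class TestPrincipal:
    def test_diagonal_tensor(self):
        p = principal_strains(np.diag([-0.01, 0.0, 0.0]))
        assert p[2] == pytest.approx(-0.01)
        assert p[0] == pytest.approx(0.0)

    def test_hydrostatic(self):
        p = principal_strains(0.003 * np.eye(3))
        np.testing.assert_allclose(p, 0.003)

    def test_matches_characteristic_polynomial_roots(self):
        rng = np.random.default_rng(9)
        M = rng.standard_normal((3, 3))
        t = 0.01 * (M + M.T)
        p = principal_strains(t)
        # oracle: roots of det(t - x I) via the cubic's coefficients
        i1 = np.trace(t)
        i2 = 0.5 * (np.trace(t) ** 2 - np.trace(t @ t))
        i3 = np.linalg.det(t)
        roots = np.sort(np.roots([1.0, -i1, i2, -i3]).real)[::-1]
        np.testing.assert_allclose(p, roots, atol=1e-10)

    def test_ordering_invariant(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            M = rng.standard_normal((3, 3))
            p = principal_strains(0.01 * (M + M.T))
            assert p[0] >= p[1] >= p[2]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            principal_strains(np.full((3, 3), np.nan))


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert von_mises(0.005 * np.eye(3)) == pytest.approx(0.0, abs=1e-15)

    def test_uniaxial_closed_form(self):
        # (2/3) * 0.01 = 6666.7 µε on the strain scale
        t = np.diag([-0.01, 0.0, 0.0])
        assert von_mises(t) == pytest.approx(2.0 / 3.0 * 0.01, rel=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        M = rng.standard_normal((3, 3))
        t = 0.01 * (M + M.T)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        assert von_mises(q @ t @ q.T) == pytest.approx(von_mises(t), abs=1e-10)


class TestMaskNodes:
    def test_full_mask_is_identity(self):
        A = 0.005 * np.eye(3)
        strain = differentiate(field_from_gradient(A))
        mask = BinaryMask(np.ones((64, 64, 64), dtype=bool), 39.0)
        out = mask_nodes(strain, mask)
        np.testing.assert_array_equal(out.included, strain.included)

    def test_node_in_cyst_removed(self):
        A = 0.005 * np.eye(3)
        strain = differentiate(field_from_gradient(A))
        data = np.ones((64, 64, 64), dtype=bool)
        x, y, z = np.ogrid[:64, :64, :64]
        data[(x - 32) ** 2 + (y - 32) ** 2 + (z - 32) ** 2 <= 12**2] = False
        out = mask_nodes(strain, BinaryMask(data, 39.0), coverage_cutoff=0.3)
        assert not out.included[2, 2, 2]  # node at voxel (32,32,32)
        assert out.included[0, 0, 0]

    def test_removed_count_matches_bruteforce_coverage(self):
        rng = np.random.default_rng(12)
        data = rng.random((64, 64, 64)) > 0.7
        mask = BinaryMask(data, 39.0)
        A = 0.005 * np.eye(3)
        strain = differentiate(field_from_gradient(A))
        cutoff = 0.28
        out = mask_nodes(strain, mask, coverage_cutoff=cutoff)
        grid = strain.grid
        removed_brute = 0
        half = grid.ns // 2
        for i, x in enumerate(grid.node_coords[0]):
            for j, y in enumerate(grid.node_coords[1]):
                for k, z in enumerate(grid.node_coords[2]):
                    sub = data[
                        max(x - half, 0): x + half + 1,
                        max(y - half, 0): y + half + 1,
                        max(z - half, 0): z + half + 1,
                    ]
                    if sub.mean() < cutoff:
                        removed_brute += 1
        assert int((~out.included).sum()) == removed_brute

    def test_all_removed_is_an_error(self):
        A = 0.005 * np.eye(3)
        strain = differentiate(field_from_gradient(A))
        empty_ish = BinaryMask(np.zeros((64, 64, 64), dtype=bool), 39.0)
        with pytest.raises(ValueError, match="every node"):
            mask_nodes(strain, empty_ish)


class TestStrainIO:
    def test_hdf5_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        A = 0.01 * rng.standard_normal((3, 3))
        strain = differentiate(field_from_gradient(A))
        path = tmp_path / "strain.h5"
        save_strain(strain, path)
        back = load_strain(path)
        np.testing.assert_allclose(back.eps, strain.eps)
        np.testing.assert_allclose(back.principal, strain.principal)
        np.testing.assert_array_equal(back.included, strain.included)

    def test_csv_export_lists_all_nodes(self, tmp_path):
        strain = differentiate(field_from_gradient(0.001 * np.eye(3)))
        path = tmp_path / "strain.csv"
        strain.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 + strain.grid.n_nodes
        header = lines[0].split(",")
        for name in COMPONENTS:
            assert name in header
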