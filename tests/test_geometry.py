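"""Unit-cell algebra, normalization, and motif-cloud construction."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from ellipack import (
    CellParameters,
    CrystalCentroids,
    build_motif_cloud,
    cell_matrix,
    normalization_map,
)
from conftest import random_cell


def triple_product_volume(cell):
    """Independent volume oracle: explicit triple product of cell vectors."""
    A = cell_matrix(cell)
    a, b, c = A[:, 0], A[:, 1], A[:, 2]
    return abs(np.dot(a, np.cross(b, c)))


class TestCellMatrix:
    def test_cubic_cell_is_scaled_identity(self):
        A = cell_matrix(CellParameters(0.5, 0.5, 0.5, 90, 90, 90))
        assert np.allclose(A, 0.5 * np.eye(3))
        assert np.isclose(np.linalg.det(A), 0.125)

    def test_orthorhombic_cell_is_diagonal(self):
        A = cell_matrix(CellParameters(0.3, 0.4, 0.5, 90, 90, 90))
        assert np.allclose(A, np.diag([0.3, 0.4, 0.5]))

    def test_rhombohedral_60deg_volume_matches_closed_form(self):
        cell = CellParameters(0.5, 0.5, 0.5, 60, 60, 60)
        c = np.cos(np.radians(60.0))
        expected = 0.5**3 * np.sqrt(1 - 3 * c**2 + 2 * c**3)
        assert np.isclose(abs(np.linalg.det(cell_matrix(cell))), expected)
        assert np.isclose(triple_product_volume(cell), expected)

    @pytest.mark.parametrize("seed", range(5))
    def test_volume_equals_triple_product_for_random_cells(self, seed):
        cell = random_cell(np.random.default_rng(seed))
        assert np.isclose(cell.volume, triple_product_volume(cell), rtol=1e-12)

    def test_degenerate_cell_rejected_with_parameter_names(self):
        with pytest.raises(ValueError, match="alpha"):
            CellParameters(0.5, 0.5, 0.5, 179.0, 1.0, 1.0).volume

    @pytest.mark.parametrize("bad", [dict(a=-0.1), dict(alpha=0.0), dict(gamma=180.0)])
    def test_invalid_parameters_rejected(self, bad):
        params = dict(a=0.5, b=0.5, c=0.5, alpha=90, beta=90, gamma=90)
        params.update(bad)
        with pytest.raises(ValueError):
            CellParameters(**params)


class TestNormalizationMap:
    def test_cubic_half_nm_cell_gives_fifth_identity(self, cubic_cell):
        W = normalization_map(cubic_cell, 0.1)
        assert np.allclose(W.matrix, 0.2 * np.eye(3))

    def test_maps_first_cell_vector_onto_cube_edge(self, triclinic_cell):
        A = cell_matrix(triclinic_cell)
        W = normalization_map(triclinic_cell, 0.1)
        assert np.allclose(W.matrix @ A[:, 0], [0.1, 0.0, 0.0], atol=1e-14)

    @pytest.mark.parametrize("seed", range(5))
    def test_composition_with_cell_matrix_is_alpha_identity(self, seed):
        cell = random_cell(np.random.default_rng(100 + seed))
        W = normalization_map(cell, 0.1)
        assert np.allclose(W.matrix @ cell_matrix(cell), 0.1 * np.eye(3), atol=1e-12)

    def test_identity_on_already_cubic_alpha_cell(self):
        cell = CellParameters(0.1, 0.1, 0.1, 90, 90, 90)
        assert np.allclose(normalization_map(cell, 0.1).matrix, np.eye(3), atol=1e-14)


class TestMotifCloud:
    def test_single_centroid_gives_eight_corners_anywhere(self, cubic_cell):
        at_origin = build_motif_cloud(
            CrystalCentroids(cell=cubic_cell, fractional=[[0, 0, 0]]), 0.1
        )
        off_origin = build_motif_cloud(
            CrystalCentroids(cell=cubic_cell, fractional=[[0.3, 0.3, 0.3]]), 0.1
        )
        corners = {(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)}
        for cloud in (at_origin, off_origin):
            assert len(cloud) == 8
            got = {tuple(np.round(p / 0.1).astype(int)) for p in cloud.points}
            assert got == corners

    @pytest.mark.parametrize(
        "extra,expected",
        [([[0.5, 0.5, 0.5]], 9), ([[0.5, 0.5, 0.0]], 10),
         ([[0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]], 14)],
    )
    def test_centred_motifs_have_expected_image_counts(self, cubic_cell, extra, expected):
        crystal = CrystalCentroids(cell=cubic_cell, fractional=[[0, 0, 0]] + extra)
        assert len(build_motif_cloud(crystal, 0.1)) == expected

    def test_translation_invariance_as_point_set(self, cubic_cell, rng):
        base = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]])
        ref = build_motif_cloud(CrystalCentroids(cell=cubic_cell, fractional=base), 0.1)
        for _ in range(5):
            shift = rng.uniform(0, 1, 3)
            cloud = build_motif_cloud(
                CrystalCentroids(cell=cubic_cell, fractional=base + shift), 0.1
            )
            a = sorted(map(tuple, np.round(ref.points, 12)))
            b = sorted(map(tuple, np.round(cloud.points, 12)))
            assert np.allclose(a, b, atol=1e-9)

    def test_a_centred_setting_congruent_to_c_motif(self, cubic_cell):
        """(0,1/2,1/2) centring must give the base-centred motif rotated 90°."""
        a_centred = build_motif_cloud(
            CrystalCentroids(cell=cubic_cell, fractional=[[0, 0, 0], [0, 0.5, 0.5]]), 0.1
        )
        c_centred = build_motif_cloud(
            CrystalCentroids(cell=cubic_cell, fractional=[[0, 0, 0], [0.5, 0.5, 0]]), 0.1
        )
        assert len(a_centred) == len(c_centred) == 10
        assert np.allclose(
            np.sort(pdist(a_centred.points)), np.sort(pdist(c_centred.points)), atol=1e-12
        )

    def test_empty_centroids_rejected(self, cubic_cell):
        with pytest.raises(ValueError):
            CrystalCentroids(cell=cubic_cell, fractional=np.empty((0, 3)))


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    shift=st.tuples(*[st.floats(-2.0, 2.0) for _ in range(3)]),
    lengths=st.tuples(*[st.floats(0.3, 1.2) for _ in range(3)]),
)
def test_motif_cloud_invariant_under_any_common_shift(shift, lengths):
    cell = CellParameters(*lengths, 90.0, 90.0, 90.0)
    base = np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.0]])
    ref = build_motif_cloud(CrystalCentroids(cell=cell, fractional=base), 0.1)
    moved = build_motif_cloud(
        CrystalCentroids(cell=cell, fractional=base + np.asarray(shift)), 0.1
    )
    a = sorted(map(tuple, np.round(ref.points, 9)))
    b = sorted(map(tuple, np.round(moved.points, 9)))
    assert np.allclose(a, b, atol=1e-8)
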