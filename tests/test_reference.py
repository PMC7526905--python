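"""Reference motifs, diagrams, ellipsoids and packing fractions."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from ellipack import (
    LatticeType,
    bottleneck_distance,
    motif_points,
    packing_fraction,
    reference_diagrams,
    reference_ellipsoid,
)
from ellipack.reference import C_X, C_Y, C_Z, centroids_per_cell, fractional_motif

ALPHA = 0.1
SQ2, SQ3, SQ6 = np.sqrt(2.0), np.sqrt(3.0), np.sqrt(6.0)

# analytic single-cell motif diagrams, distinct (birth, death) values in
# units of the cube side: derived from the Čech geometry (half nearest
# neighbour distances in q=0; face/cell circumradii in q=1,2)
ANALYTIC_Q0 = {
    "P": [(0.0, 0.5), (0.0, np.inf)],
    "C": [(0.0, 1 / (2 * SQ2)), (0.0, 0.5), (0.0, np.inf)],
    "I": [(0.0, SQ3 / 4), (0.0, np.inf)],
    "F": [(0.0, 1 / (2 * SQ2)), (0.0, np.inf)],
}
ANALYTIC_FULL = {
    "P": {1: [(0.5, 1 / SQ2)], 2: [(1 / SQ2, SQ3 / 2)]},
    "F": {1: [(1 / (2 * SQ2), 1 / SQ6)], 2: [(1 / SQ6, SQ3 / 4), (1 / SQ6, 0.5)]},
}


class TestMotifPoints:
    @pytest.mark.parametrize("sym,count", [("P", 8), ("C", 10), ("I", 9), ("F", 14)])
    def test_point_counts(self, sym, count):
        assert len(motif_points(sym, ALPHA)) == count

    def test_p_motif_is_cube_corners(self):
        got = {tuple(np.round(p / ALPHA).astype(int)) for p in motif_points("P", ALPHA).points}
        assert got == {(i, j, k) for i in (0, 1) for j in (0, 1) for k in (0, 1)}

    def test_i_motif_contains_body_centre(self):
        pts = motif_points("I", ALPHA).points
        assert any(np.allclose(p, [0.05, 0.05, 0.05]) for p in pts)

    def test_f_minimum_pairwise_distance_is_half_face_diagonal(self):
        d = pdist(motif_points("F", ALPHA).points)
        assert d.min() == pytest.approx(ALPHA / SQ2, abs=1e-15)

    def test_invalid_type_rejected(self):
        with pytest.raises(ValueError):
            LatticeType("Q")
        with pytest.raises(ValueError):
            LatticeType("P", "z")
        with pytest.raises(ValueError):
            LatticeType("C")  # C without an axis


class TestReferenceDiagrams:
    @pytest.mark.parametrize("sym", ["P", "C", "I", "F"])
    def test_q0_distinct_values_match_analytic_list(self, sym):
        got = reference_diagrams(sym, ALPHA).d0.distinct(tol=1e-10)
        want = np.asarray(ANALYTIC_Q0[sym]) * ALPHA
        want[np.isinf(want)] = np.inf
        assert got.shape == want.shape
        finite = np.isfinite(want)
        assert np.allclose(got[finite], want[finite], atol=1e-9 * ALPHA)

    @pytest.mark.parametrize("sym", ["P", "F"])
    @pytest.mark.parametrize("q", [1, 2])
    def test_higher_degree_distinct_values_where_realised_in_one_cell(self, sym, q):
        got = reference_diagrams(sym, ALPHA)[q].distinct(tol=1e-10)
        want = np.asarray(ANALYTIC_FULL[sym][q]) * ALPHA
        assert got.shape == want.shape
        assert np.allclose(np.sort(got, axis=0), np.sort(want, axis=0), atol=1e-9 * ALPHA)

    def test_scale_relation(self):
        small, big = reference_diagrams("I", 0.1), reference_diagrams("I", 0.3)
        for q in range(3):
            assert np.allclose(3.0 * small[q].pairs, big[q].pairs, atol=1e-12)

    def test_c_centring_axes_are_indistinguishable_by_diagrams(self):
        for q in range(3):
            for other in (C_X, C_Y):
                d = bottleneck_distance(
                    reference_diagrams(C_Z, ALPHA)[q], reference_diagrams(other, ALPHA)[q]
                )
                assert d <= 1e-12


class TestReferenceEllipsoid:
    def test_p_is_half_cell_sphere(self):
        assert np.allclose(reference_ellipsoid("P", ALPHA).radii, 0.05)

    def test_i_sphere_radius_is_half_nearest_neighbour_distance(self):
        r = reference_ellipsoid("I", ALPHA).radii
        dmin = pdist(motif_points("I", ALPHA).points).min()
        assert np.allclose(r, dmin / 2)
        assert r[0] == pytest.approx(SQ3 * ALPHA / 4)

    def test_c_spheroid_axis_follows_centring_axis(self):
        for t, axis in ((C_X, 0), (C_Y, 1), (C_Z, 2)):
            radii = np.diag(reference_ellipsoid(t, ALPHA).matrix) ** -0.5
            assert radii[axis] == pytest.approx(ALPHA / 2)
            others = np.delete(radii, axis)
            assert np.allclose(others, SQ2 * ALPHA / 4)

    @pytest.mark.parametrize("sym", ["P", "C", "I", "F"])
    def test_contacts_tight_and_no_overlap(self, sym):
        """Ellipsoids touch along nearest-neighbour directions, never overlap.

        The quadratic form evaluated at half the separation vector is 1 at
        contact and > 1 for non-touching pairs.
        """
        t = C_Z if sym == "C" else sym
        pts = motif_points(t, ALPHA).points
        R = reference_ellipsoid(t, ALPHA).matrix
        forms = []
        for i in range(len(pts)):
            for j in range(i + 1, len(pts)):
                h = (pts[j] - pts[i]) / 2
                forms.append(h @ R @ h)
        forms = np.asarray(forms)
        assert forms.min() == pytest.approx(1.0, abs=1e-9)  # tight contact
        assert np.all(forms >= 1.0 - 1e-9)  # no interpenetration


class TestPackingFraction:
    def test_face_centred_is_closest_packing(self):
        assert packing_fraction("F") == pytest.approx(np.pi / np.sqrt(18), abs=1e-12)

    def test_primitive_is_simple_cubic(self):
        assert packing_fraction("P") == pytest.approx(np.pi / 6, abs=1e-12)

    def test_body_centred_closed_form(self):
        assert packing_fraction("I") == pytest.approx(np.sqrt(3) * np.pi / 8, abs=1e-12)

    def test_independent_of_cube_side(self):
        # packing_fraction uses the reference ellipsoid at unit side; check
        # against an explicit computation at another side
        for sym in "PCIF":
            t = C_Z if sym == "C" else sym
            r = reference_ellipsoid(t, 0.37).radii
            direct = centroids_per_cell(t) * 4 / 3 * np.pi * np.prod(r) / 0.37**3
            assert packing_fraction(t) == pytest.approx(direct, abs=1e-12)

    def test_fractional_motif_counts(self):
        for sym, z in (("P", 1), ("C", 2), ("I", 2), ("F", 4)):
            t = C_Z if sym == "C" else sym
            assert fractional_motif(t).shape[0] == z == centroids_per_cell(t)
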