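"""Solute/slab orientation vectors, order parameter and binned profiles.

The greedy sign-flip accumulation in slab_vector is checked against an
exhaustive 2^n enumeration of all sign assignments on small fragment
sets; analytic order-parameter values and rotational invariance pin the
rest down.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slabpmf import (Configuration, CylinderSpec, OrientationRecord,
                     make_oriented_chain, order_parameter,
                     orientation_profile, select_cylinder, slab_vector,
                     solute_vector)
from slabpmf.orientation import DegenerateGeometryError, EmptyRegionError


def _rotation(axis, angle_deg):
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(t) * k + (1 - np.cos(t)) * (k @ k)


class TestSoluteVector:
    def test_collinear_chain_along_z(self):
        coords = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        np.testing.assert_allclose(solute_vector(coords), [0, 0, 1], atol=1e-12)

    def test_zigzag_transverse_components_cancel(self):
        """Ideal all-anti zigzag along +x: every 1,3-vector is axial."""
        chain = make_oriented_chain(8, tilt=90.0)  # axis rotated z->x
        v = solute_vector(chain)
        np.testing.assert_allclose(v, [1, 0, 0], atol=1e-9)

    def test_three_atoms_single_vector(self):
        coords = np.array([[0.0, 0, 0], [1.0, 1, 0], [2.0, 0, 0]])
        np.testing.assert_allclose(solute_vector(coords), [1, 0, 0], atol=1e-12)

    def test_tail_to_head_direction(self):
        chain = make_oriented_chain(8, tilt=0.0)
        assert solute_vector(chain)[2] > 0          # tail at low z, head high
        assert solute_vector(chain[::-1])[2] < 0    # reversed order flips it

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError):
            solute_vector(np.zeros((2, 3)))

    def test_coincident_atoms_degenerate(self):
        coords = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 0]])
        with pytest.raises(DegenerateGeometryError):
            solute_vector(coords)


def _brute_force_max_resultant(vs):
    """Exhaustive sign search maximising |Σ s_i v_i| (oracle, n <= 15)."""
    best = None
    for signs in itertools.product([1.0, -1.0], repeat=len(vs)):
        r = (np.asarray(signs)[:, None] * vs).sum(axis=0)
        mag = np.linalg.norm(r)
        if best is None or mag > best[0]:
            best = (mag, r)
    _, r = best
    if r[2] < 0:
        r = -r
    return r / np.linalg.norm(r)


class TestSlabVector:
    def test_antiparallel_pair_reinforces(self):
        vs = np.array([[0.0, 0, 1], [0.0, 0, -1]])
        v = slab_vector(vs)
        np.testing.assert_allclose(v, [0, 0, 1], atol=1e-12)

    def test_single_negative_z_vector_is_reversed(self):
        v = slab_vector(np.array([[0.0, 0.3, -0.9]]))
        assert v[2] > 0

    def test_identical_vectors_unchanged(self):
        vs = np.tile([0.6, 0.0, 0.8], (5, 1))
        np.testing.assert_allclose(slab_vector(vs), [0.6, 0, 0.8], atol=1e-12)

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_greedy_close_to_exhaustive_oracle(self, n, rng):
        """Greedy flips recover the exhaustive-maximisation direction for
        fragment sets clustered about a common axis (the physical regime)."""
        base = np.array([0.3, 0.1, 0.95])
        base /= np.linalg.norm(base)
        for trial in range(10):
            vs = base + 0.3 * rng.standard_normal((n, 3))
            vs *= np.where(rng.random(n) < 0.5, -1.0, 1.0)[:, None]
            vs /= np.linalg.norm(vs, axis=1)[:, None]
            greedy = slab_vector(vs.copy())
            oracle = _brute_force_max_resultant(vs)
            assert abs(np.dot(greedy, oracle)) > 0.99

    def test_empty_fragments_raise(self):
        with pytest.raises(EmptyRegionError):
            slab_vector([])


class TestSelectCylinder:
    def _system(self, centers_xyz, box=(60.0, 60.0, 120.0)):
        """One 3-bead vertical chain per requested central-atom position."""
        pos, mols = [], []
        for m, c in enumerate(centers_xyz):
            c = np.asarray(c, dtype=float)
            pos.extend([c - [0, 0, 1.0], c, c + [0, 0, 1.0]])
            mols.extend([m] * 3)
        n = len(pos)
        return Configuration(
            positions=np.array(pos), species=np.array(["PE"] * n),
            masses=np.ones(n), charges=np.zeros(n),
            molecule_ids=np.array(mols), box=np.array(box))

    CYL = CylinderSpec(radius=13.0, z_lower_offset_from_slab_com=18.0,
                       z_upper=80.0)

    def test_radius_boundary_inclusive_exclusive(self):
        cfg = self._system([[30 + 12.9, 30, 75.0], [30 + 13.1, 30, 75.0]])
        frags = select_cylinder(cfg, (30.0, 30.0), self.CYL, slab_com_z=50.0)
        assert len(frags) == 1
        np.testing.assert_allclose(frags[0][1], [30 + 12.9, 30, 75.0])

    def test_z_window(self):
        # slab COM at 50: lower bound 68, upper 80
        cfg = self._system([[30, 30, 67.0], [30, 30, 69.0], [30, 30, 81.0]])
        frags = select_cylinder(cfg, (30.0, 30.0), self.CYL, slab_com_z=50.0)
        assert len(frags) == 1
        assert frags[0][1][2] == pytest.approx(69.0)

    def test_minimum_image_in_xy(self):
        # atom across the periodic boundary: x=59, axis at x=2 -> distance 3
        cfg = self._system([[59.0, 30.0, 75.0]])
        frags = select_cylinder(cfg, (2.0, 30.0), self.CYL, slab_com_z=50.0)
        assert len(frags) == 1

    def test_empty_region_allowed(self):
        cfg = self._system([[30, 30, 40.0]])
        assert select_cylinder(cfg, (30.0, 30.0), self.CYL,
                               slab_com_z=50.0) == []


class TestOrderParameter:
    def test_parallel_is_one(self):
        theta, s = order_parameter([0, 0, 1.0], [0, 0, 1.0])
        assert theta == pytest.approx(0.0)
        assert s == pytest.approx(1.0)

    def test_perpendicular_is_minus_half(self):
        theta, s = order_parameter([0, 0, 1.0], [1.0, 0, 0])
        assert theta == pytest.approx(90.0)
        assert s == pytest.approx(-0.5)

    def test_magic_angle_is_zero(self):
        t = np.radians(54.7356103)
        theta, s = order_parameter([0, 0, 1.0], [np.sin(t), 0, np.cos(t)])
        assert s == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_in_arguments(self, rng):
        v1, v2 = rng.standard_normal((2, 3))
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        assert order_parameter(v1, v2) == order_parameter(v2, v1)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            order_parameter([0, 0, 0], [0, 0, 1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.floats(1.0, 359.0))
    def test_joint_rotation_invariance_and_bounds(self, seed, angle):
        """Rotating both vectors together preserves θ and S_v; S_v stays
        within [−0.5, 1] for any pair."""
        r = np.random.default_rng(seed)
        v1, v2, axis = r.standard_normal((3, 3))
        if min(np.linalg.norm(v1), np.linalg.norm(v2)) < 1e-3 \
                or np.linalg.norm(axis) < 1e-3:
            return
        v1 /= np.linalg.norm(v1)
        v2 /= np.linalg.norm(v2)
        rot = _rotation(axis, angle)
        t0, s0 = order_parameter(v1, v2)
        t1, s1 = order_parameter(rot @ v1, rot @ v2)
        assert t1 == pytest.approx(t0, abs=1e-7)
        assert s1 == pytest.approx(s0, abs=1e-9)
        assert -0.5 - 1e-12 <= s0 <= 1.0 + 1e-12


def _record(theta, xi, frame=0):
    t = np.radians(theta)
    v1 = np.array([np.sin(t), 0.0, np.cos(t)])
    v2 = np.array([0.0, 0.0, 1.0])
    _, s = order_parameter(v1, v2)
    return OrientationRecord(frame=frame, v1=v1, v2=v2, theta=theta,
                             s_v=s, xi=xi)


class TestOrientationProfile:
    def test_aligned_records_mean_one_zero_width(self):
        recs = [_record(0.0, 1.0, i) for i in range(20)]
        prof = orientation_profile(recs, np.array([0.0, 2.0]))
        assert prof["mean_s_v"][0] == pytest.approx(1.0)
        assert prof["ci_upper"][0] - prof["ci_lower"][0] == pytest.approx(0.0)

    def test_isotropic_orientations_average_to_zero(self, rng):
        """E[cos²θ] = 1/3 for uniform directions ⇒ S_v → 0."""
        n = 100_000
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        cos2 = v[:, 2] ** 2
        s_v = (3 * cos2.mean() - 1) / 2
        assert abs(s_v) < 0.01

    def test_two_replica_t_interval(self):
        """Bin mean is the average of replica means; CI uses 1 df."""
        rep1 = [_record(0.0, 0.5, i) for i in range(10)]       # S_v = 1
        rep2 = [_record(90.0, 0.5, i) for i in range(10)]      # S_v = -0.5
        prof = orientation_profile([rep1, rep2], np.array([0.0, 1.0]),
                                   confidence=0.95)
        m1, m2 = 1.0, -0.5
        assert prof["mean_s_v"][0] == pytest.approx((m1 + m2) / 2)
        from scipy import stats
        sem = np.std([m1, m2], ddof=1) / np.sqrt(2)
        half = stats.t.ppf(0.975, df=1) * sem
        assert prof["ci_upper"][0] - prof["mean_s_v"][0] == pytest.approx(half)

    def test_empty_bin_is_nan(self):
        recs = [_record(10.0, 0.5)]
        prof = orientation_profile(recs, np.array([0.0, 1.0, 2.0]))
        assert np.isnan(prof["mean_s_v"][1])

    def test_angle_quartiles(self):
        recs = [_record(t, 0.5, i) for i, t in enumerate([10, 20, 30, 40, 50])]
        prof = orientation_profile(recs, np.array([0.0, 1.0]))
        np.testing.assert_allclose(prof["theta_quartiles"][0], [20, 30, 40])
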