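import numpy as np
import pytest

from needleplan.geometry import points_line_distance
from needleplan.hough import (
    anchor_from_params,
    build_direction_set,
    extract_lines,
    forward_transform,
    line_to_needle,
    plane_basis,
    vote,
)


class TestDirectionSet:
    def test_vertex_counts_after_antipodal_halving(self):
        assert len(build_direction_set(0)) == 6            # (10*4^0+2)/2
        assert len(build_direction_set(1)) == 21           # (10*4+2)/2
        assert len(build_direction_set(2)) == 81

    def test_level6_count_and_resolution(self, dirset6):
        assert len(dirset6) == (10 * 4**6 + 2) // 2 == 20481
        assert dirset6.mean_neighbour_deg <= 1.3

    def test_directions_unit_and_hemisphere(self, dirset2):
        d = dirset2.directions
        assert np.allclose(np.linalg.norm(d, axis=1), 1.0, atol=1e-12)
        assert np.all(d[:, 2] >= -1e-12)
        # pairwise distinct under antipodal identification
        dots = np.abs(d @ d.T) - np.eye(len(d))
        assert dots.max() < 1.0 - 1e-9

    def test_level_out_of_range(self):
        with pytest.raises(ValueError):
            build_direction_set(9)
        with pytest.raises(ValueError):
            build_direction_set(-1)


class TestTransform:
    def test_forward_at_z_direction(self):
        assert forward_transform((3, 4, 7), (0, 0, 1)) == pytest.approx((3, 4))

    def test_point_along_direction_maps_to_origin(self, rng):
        b = rng.normal(size=3)
        b /= np.linalg.norm(b)
        if b[2] < 0:
            b = -b
        assert forward_transform(2.7 * b, b) == pytest.approx((0, 0), abs=1e-9)

    def test_anchor_trivial_cases(self):
        assert anchor_from_params(3, 4, (0, 0, 1)) == pytest.approx([3, 4, 0])
        assert anchor_from_params(0, 0, (0.6, 0, 0.8)) == pytest.approx([0, 0, 0])

    def test_roundtrip_and_orthogonality(self, rng):
        """forward/inverse roundtrip identity and anchor-plane orthogonality
        for 1000 random point/direction pairs."""
        for _ in range(1000):
            p = rng.uniform(-100, 100, 3)
            b = rng.normal(size=3)
            b /= np.linalg.norm(b)
            if b[2] < 0:
                b = -b
            xp, yp = forward_transform(p, b)
            a = anchor_from_params(xp, yp, b)
            assert abs(np.dot(a, b)) < 1e-9
            assert forward_transform(a, b) == pytest.approx((xp, yp), abs=1e-9)
            e1, e2 = plane_basis(b)
            assert (np.dot(p, e1), np.dot(p, e2)) == pytest.approx((xp, yp), abs=1e-9)

    def test_anchor_is_closest_line_point_to_origin(self, rng):
        for _ in range(30):
            p = rng.uniform(-50, 50, 3)
            b = rng.normal(size=3)
            b /= np.linalg.norm(b)
            if b[2] < 0:
                b = -b
            a = anchor_from_params(*forward_transform(p, b), b)
            t = np.linspace(-200, 200, 20001)[:, None]
            sampled = a + t * b
            dmin = np.linalg.norm(sampled, axis=1).min()
            assert np.linalg.norm(a) <= dmin + 1e-6

    def test_singular_direction_rejected(self):
        with pytest.raises(ValueError):
            plane_basis(np.array([0.0, 0.0, -1.0]))


class TestVoting:
    def test_single_seed_conservation(self, dirset2):
        acc = vote(np.array([[3.0, -2.0, 7.0]]), dirset2, 0.5)
        assert acc.total_votes == len(dirset2)
        assert acc.counts.max() == 1

    def test_total_votes_is_seeds_times_directions(self, dirset2, rng):
        seeds = rng.uniform(-20, 20, (9, 3))
        acc = vote(seeds, dirset2, 0.5)
        assert acc.total_votes == 9 * len(dirset2)

    def test_collinear_seeds_fill_one_cell(self, dirset2):
        b = dirset2.directions[17]
        seeds = np.array([k * 4.0 * b for k in range(1, 6)])
        acc = vote(seeds, dirset2, 0.5)
        d, ix, iy, votes = acc.peak()
        assert votes == 5
        assert d == 17

    def test_counts_match_bruteforce_double_loop(self, dirset2, rng):
        """Accumulator equals an exhaustive per-seed/per-direction recount."""
        seeds = rng.uniform(-15, 15, (7, 3))
        step = 0.7
        acc = vote(seeds, dirset2, step)
        expected = {}
        for s in seeds:
            for d, b in enumerate(dirset2.directions):
                xp, yp = forward_transform(s, b)
                ix = int(np.floor((xp - acc.range_min) / step))
                iy = int(np.floor((yp - acc.range_min) / step))
                key = (d * acc.n_bins + ix) * acc.n_bins + iy
                expected[key] = expected.get(key, 0) + 1
        got = dict(zip(acc.keys.tolist(), acc.counts.tolist()))
        assert got == expected

    def test_dense_slice_agrees_with_sparse(self, dirset2, rng):
        seeds = rng.uniform(-10, 10, (5, 3))
        acc = vote(seeds, dirset2, 1.0)
        sl = acc.counts_for_direction(3)
        assert sl.sum() == 5

    def test_empty_and_bad_inputs(self, dirset2):
        with pytest.raises(ValueError):
            vote(np.empty((0, 3)), dirset2, 0.5)
        with pytest.raises(ValueError):
            vote(np.ones((2, 3)), dirset2, -1.0)


class TestExtraction:
    def test_two_disjoint_collinear_groups(self, dirset6):
        g1 = np.array([[0.0, 0.0, 5.0 * k] for k in range(5)])
        g2 = np.array([[6.0 * k, 40.0, 0.0] for k in range(3)])
        cands = extract_lines(np.vstack([g1, g2]), dirset6, 0.2, 1.0, 2)
        sizes = sorted(len(c.assigned_seed_ids) for c in cands)
        assert sizes == [3, 5]
        for c in cands:
            assert c.rms_residual < 1e-6
            assert c.votes == len(c.assigned_seed_ids)

    def test_single_seed_gives_singleton(self, dirset2):
        cands = extract_lines(np.array([[1.0, 2.0, 3.0]]), dirset2)
        assert len(cands) == 1
        assert cands[0].assigned_seed_ids == [0]

    def test_partition_property(self, dirset6, rng):
        seeds = rng.uniform(-20, 20, (12, 3))
        cands = extract_lines(seeds, dirset6)
        ids = sorted(i for c in cands for i in c.assigned_seed_ids)
        assert ids == list(range(12))

    def test_noisy_line_recovery(self, dirset6, rng):
        """Seeds on a known line with <=0.3 mm uniform noise are grouped into
        one candidate within 0.5 degrees / 0.3 mm of the truth."""
        d = rng.normal(size=3)
        d /= np.linalg.norm(d)
        p0 = rng.uniform(-20, 20, 3)
        t = np.arange(6) * 7.0
        seeds = p0 + t[:, None] * d + rng.uniform(-0.3, 0.3, (6, 3))
        cands = extract_lines(seeds, dirset6, 0.2, 1.0, 2)
        assert len(cands) == 1
        got = cands[0].line.direction
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(got, d)), 0, 1)))
        assert ang < 0.5
        centroid = seeds.mean(axis=0)
        from needleplan.geometry import point_line_distance
        assert point_line_distance(centroid, cands[0].line.point_at(0),
                                   cands[0].line.point_at(1)) < 0.3

    def test_exact_collinear_recovery_along_lattice_directions(self, dirset6, rng):
        """k >= 3 exactly collinear points aligned with any level-6 direction
        come back as one candidate with < 1e-6 mm residual."""
        for idx in rng.integers(0, len(dirset6), size=3):
            b = dirset6.directions[idx]
            p0 = rng.uniform(-30, 30, 3)
            seeds = p0 + np.arange(4)[:, None] * 6.0 * b
            cands = extract_lines(seeds, dirset6, 0.2, 1.0, 2)
            assert len(cands) == 1
            assert cands[0].rms_residual < 1e-6


class TestLineToNeedle:
    def test_sign_rule_and_arithmetic(self, dirset2):
        cands = extract_lines(np.array([[0.0, 0.0, 42.0]]), dirset2)
        cand = cands[0]
        cand.line = type(cand.line)(anchor=(0, 0, 0), direction=(0, 0, 1))
        nd = line_to_needle(cand, np.array([[0.0, 0.0, 42.0]]), [0],
                            needle_length=200.0, entry_direction_hint=(0, 0, -1))
        assert nd.p_t == pytest.approx([0, 0, 42])
        assert nd.p_s == pytest.approx([0, 0, -158])

    def test_seed_at_anchor_becomes_tip(self, dirset2):
        from needleplan.hough import LineCandidate
        from needleplan.geometry import Line3
        cand = LineCandidate(line=Line3((0, 0, 0), (0, 0, 1)), votes=1,
                             assigned_seed_ids=[0], rms_residual=0.0)
        nd = line_to_needle(cand, np.array([[0.0, 0.0, 0.0]]), [0], 100.0, (0, 0, 1))
        assert nd.p_t == pytest.approx([0, 0, 0], abs=1e-12)

    def test_postconditions_random(self, dirset6, rng):
        """Fixed length; all seeds lie axially between hub and tip; hub on
        the entry side."""
        for _ in range(5):
            b = dirset6.directions[rng.integers(len(dirset6))]
            p0 = rng.uniform(-20, 20, 3)
            seeds = p0 + rng.uniform(0, 30, (4, 1)) * b
            cands = extract_lines(seeds, dirset6, 0.2, 1.0, 2)
            assert len(cands) == 1
            nd = line_to_needle(cands[0], seeds, [0, 1, 2, 3], 200.0, (0, 0, 1))
            assert np.linalg.norm(nd.p_s - nd.p_t) == pytest.approx(200.0, abs=1e-9)
            u = nd.direction
            ax = (seeds - nd.p_s) @ u
            assert np.all(ax >= -1e-6) and np.all(ax <= 200.0 + 1e-6)
            assert np.dot(nd.p_s - nd.p_t, [0, 0, 1]) >= -1e-9

    def test_too_short_needle_rejected(self, dirset6):
        seeds = np.array([[0.0, 0.0, 10.0 * k] for k in range(5)])
        cands = extract_lines(seeds, dirset6, 0.2, 1.0, 2)
        with pytest.raises(ValueError):
            line_to_needle(cands[0], seeds, list(range(5)), 30.0, (0, 0, 1))
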