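"""Trajectory linking: assignment optimality, memory, determinism."""

import itertools

import numpy as np
import pytest

import paratrack as pt
from paratrack.detect import Detection
from paratrack.link import SubnetOversizeError, link


def D(frame, x, y, mass=100.0):
    return Detection(frame=frame, t_s=float(frame), x_px=float(x), y_px=float(y), mass=mass, size_px=1.0)


def brute_force_cost(prev, new, search_range, gap=1.0):
    """Minimum total cost over all partial matchings of prev->new positions.

    Matching pair cost is squared distance (allowed only within
    search_range * gap); every unmatched element on either side costs
    search_range**2.  Exhaustive over all injections, so only for tiny sets.
    """
    penalty = search_range**2
    na, nd = len(prev), len(new)
    best = np.inf
    for k in range(min(na, nd) + 1):
        for rows in itertools.combinations(range(na), k):
            for cols in itertools.permutations(range(nd), k):
                cost = 0.0
                ok = True
                for i, j in zip(rows, cols):
                    d2 = (prev[i][0] - new[j][0]) ** 2 + (prev[i][1] - new[j][1]) ** 2
                    if d2 > (search_range * gap) ** 2:
                        ok = False
                        break
                    cost += d2
                if not ok:
                    continue
                cost += penalty * (na - k) + penalty * (nd - k)
                best = min(best, cost)
    return best


def linked_cost(trajs, detections, search_range):
    """Total frame-to-frame cost realised by a linking result."""
    penalty = search_range**2
    cost = 0.0
    frames = sorted({d.frame for d in detections})
    by_frame_pts = {f: [] for f in frames}
    for t in trajs:
        for k in range(t.n_points):
            by_frame_pts[int(t.frames[k])].append((t.particle_id, t.x_px[k], t.y_px[k]))
    for fa, fb in zip(frames[:-1], frames[1:]):
        prev = {pid: (x, y) for pid, x, y in by_frame_pts[fa]}
        new = {pid: (x, y) for pid, x, y in by_frame_pts[fb]}
        matched = set(prev) & set(new)
        for pid in matched:
            cost += (prev[pid][0] - new[pid][0]) ** 2 + (prev[pid][1] - new[pid][1]) ** 2
        cost += penalty * (len(prev) - len(matched)) + penalty * (len(new) - len(matched))
    return cost


class TestLinkBasics:
    def test_two_distant_particles_stay_two_trajectories(self):
        dets = []
        for f in range(20):
            dets.append(D(f, 10 + 0.5 * f, 10))
            dets.append(D(f, 100 - 0.5 * f, 100))
        trajs = link(dets, pt.LinkParams(search_range_px=5.0))
        assert len(trajs) == 2
        assert all(t.n_points == 20 for t in trajs)

    def test_memory_bridges_a_gap(self):
        dets = [D(f, 10 + f, 10) for f in range(5)] + [D(f, 10 + f, 10) for f in range(8, 12)]
        trajs = link(dets, pt.LinkParams(search_range_px=5.0, memory_frames=3))
        assert len(trajs) == 1
        assert trajs[0].start_frame == 0 and trajs[0].end_frame == 11
        assert np.all(np.diff(trajs[0].frames) <= 3 + 1)

    def test_zero_memory_fragments_on_a_single_miss(self):
        dets = [D(f, 10 + f, 10) for f in range(5)] + [D(f, 10 + f, 10) for f in range(6, 10)]
        trajs = link(dets, pt.LinkParams(search_range_px=5.0, memory_frames=0))
        assert len(trajs) == 2

    def test_every_detection_in_exactly_one_trajectory(self):
        rng = np.random.default_rng(0)
        dets = []
        for f in range(30):
            for _ in range(rng.integers(0, 6)):
                dets.append(D(f, rng.uniform(0, 100), rng.uniform(0, 100)))
        trajs = link(dets, pt.LinkParams(search_range_px=8.0, memory_frames=2))
        assert sum(t.n_points for t in trajs) == len(dets)
        seen = set()
        for t in trajs:
            for k in range(t.n_points):
                key = (int(t.frames[k]), float(t.x_px[k]), float(t.y_px[k]))
                assert key not in seen
                seen.add(key)

    def test_deterministic_particle_ids(self):
        rng = np.random.default_rng(1)
        dets = [D(f, rng.uniform(0, 50), rng.uniform(0, 50)) for f in range(20) for _ in range(3)]
        a = link(dets, pt.LinkParams(search_range_px=10.0))
        b = link(dets, pt.LinkParams(search_range_px=10.0))
        assert [t.particle_id for t in a] == [t.particle_id for t in b]
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.frames, tb.frames)
            np.testing.assert_array_equal(ta.x_px, tb.x_px)

    def test_oversized_subnet_raises(self):
        dets = [D(0, i, 0) for i in range(7)] + [D(1, i + 0.1, 0) for i in range(7)]
        with pytest.raises(SubnetOversizeError):
            link(dets, pt.LinkParams(search_range_px=100.0, max_subnet_size=5))

    def test_unsorted_detections_rejected(self):
        with pytest.raises(ValueError):
            link([D(3, 0, 0), D(1, 0, 0)])


class TestAssignmentOptimality:
    @pytest.mark.parametrize("na,nd,seed", [(2, 2, 0), (3, 3, 1), (4, 3, 2), (3, 5, 3), (5, 5, 4), (6, 6, 5)])
    def test_subnet_solution_matches_brute_force(self, na, nd, seed):
        rng = np.random.default_rng(seed)
        search = 10.0
        prev = [(rng.uniform(0, 15), rng.uniform(0, 15)) for _ in range(na)]
        new = [(rng.uniform(0, 15), rng.uniform(0, 15)) for _ in range(nd)]
        dets = [D(0, x, y) for x, y in prev] + [D(1, x, y) for x, y in new]
        trajs = link(dets, pt.LinkParams(search_range_px=search, memory_frames=0, max_subnet_size=10))
        assert linked_cost(trajs, dets, search) == pytest.approx(brute_force_cost(prev, new, search))

    def test_crossing_particles_frame_by_frame_optimal(self):
        """Three crossing particles over five frames: the realised linking cost
        equals the exhaustive frame-pair optimum at every step."""
        paths = [
            [(10 + 4 * f, 10 + 4 * f) for f in range(5)],
            [(30 - 4 * f, 10 + 4 * f) for f in range(5)],
            [(20.0, 8 + 4.5 * f) for f in range(5)],
        ]
        dets = [D(f, *paths[p][f]) for f in range(5) for p in range(3)]
        search = 12.0
        trajs = link(dets, pt.LinkParams(search_range_px=search, memory_frames=0))
        total = 0.0
        for f in range(4):
            total += brute_force_cost([p[f] for p in paths], [p[f + 1] for p in paths], search)
        assert linked_cost(trajs, dets, search) == pytest.approx(total)


class TestGroundTruthScore:
    def _perfect_setup(self):
        params = pt.SwimmerParams(state_rates=pt.StateRates(0, 0, 0, 0, 0, 0),
                                  rotational_diffusion_rad2_s=0.01)
        start = np.array([[3000.0, 2500.0], [11000.0, 7500.0]])
        truth = pt.simulate_swimmers(2, 60, params=params, seed=3, initial_state=0,
                                     initial_positions_um=start)
        um_per_px = 70.0
        dets = [
            D(f, truth.x_um[s, f] / um_per_px, truth.y_um[s, f] / um_per_px)
            for f in range(truth.n_frames)
            for s in range(2)
        ]
        return truth, dets, um_per_px

    def test_perfect_detections_score_perfectly(self):
        truth, dets, um_per_px = self._perfect_setup()
        trajs = link(dets, pt.LinkParams(search_range_px=10.0))
        score = pt.link_ground_truth_score(trajs, truth, um_per_px, match_radius_px=2.0)
        assert score.mean_purity == 1.0
        assert score.mean_coverage == 1.0

    def test_identity_shuffling_lowers_purity(self):
        truth, _, um_per_px = self._perfect_setup()
        # one "trajectory" that alternates between the two swimmers' positions
        n = truth.n_frames
        swimmer = np.arange(n) % 2
        fused = pt.Trajectory(
            particle_id=0,
            frames=np.arange(n),
            t_s=truth.times_s.copy(),
            x_px=truth.x_um[swimmer, np.arange(n)] / um_per_px,
            y_px=truth.y_um[swimmer, np.arange(n)] / um_per_px,
            mass=np.ones(n),
        )
        score = pt.link_ground_truth_score([fused], truth, um_per_px, match_radius_px=2.0)
        assert score.purity[0] <= 0.51

    def test_empty_inputs_give_empty_report(self, small_truth):
        score = pt.link_ground_truth_score([], small_truth, 70.0)
        assert score.n_trajectories == 0

    def test_report_reproducible(self, small_truth):
        frames = pt.render_frames(small_truth, pt.RenderParams(), seed=2)
        dets = pt.detect_sequence(frames, 100)
        trajs = link(dets, pt.LinkParams(search_range_px=10.0))
        a = pt.link_ground_truth_score(trajs, small_truth, 70.0)
        b = pt.link_ground_truth_score(trajs, small_truth, 70.0)
        np.testing.assert_array_equal(a.purity, b.purity)
        np.testing.assert_array_equal(a.coverage, b.coverage)
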