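"""Frame-to-frame trajectory linking by minimum-cost assignment.

Detections in consecutive frames are joined Crocker–Grier style: candidate
pairs within a search radius are grouped into connected subnets, and each
subnet is solved as a minimum-cost assignment with squared-displacement
costs, where leaving a particle or a detection unmatched costs
``search_range_px**2``.  A particle that goes unmatched keeps its last
position and stays linkable for ``memory_frames`` further frames (the
allowed displacement grows linearly with the gap), then terminates.  With
``memory_frames=0`` a single missed detection fragments the trajectory —
the fragmentation regime long bulk recordings inevitably operate in.

Every detection ends up in exactly one trajectory, and identical inputs
always produce identical particle ids and memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detect import Detection

__all__ = [
    "LinkParams",
    "Trajectory",
    "SubnetOversizeError",
    "link",
    "link_ground_truth_score",
    "LinkScore",
    "trajectories_to_dataframe",
    "trajectories_from_dataframe",
]

_BIG = 1e12


class SubnetOversizeError(RuntimeError):
    """A linking subnet exceeded ``max_subnet_size``; reduce search_range_px."""


@dataclass(frozen=True)
class LinkParams:
    search_range_px: float = 15.0
    memory_frames: int = 3
    max_subnet_size: int = 30

    def __post_init__(self) -> None:
        if self.search_range_px <= 0:
            raise ValueError("search_range_px must be > 0")
        if self.memory_frames < 0:
            raise ValueError("memory_frames must be >= 0")


@dataclass
class Trajectory:
    """One linked particle: ordered detections sharing an identity."""

    particle_id: int
    frames: np.ndarray
    t_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    mass: np.ndarray

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def start_t_s(self) -> float:
        return float(self.t_s[0])

    @property
    def n_points(self) -> int:
        return len(self.frames)

    def path_length_px(self) -> float:
        """Total polyline length in pixels (gap segments included as chords)."""
        return float(np.hypot(np.diff(self.x_px), np.diff(self.y_px)).sum())


@dataclass
class _Active:
    particle_id: int
    x: float
    y: float
    last_frame: int
    points: list = field(default_factory=list)


def _solve_subnet(costs: np.ndarray, penalty: float) -> tuple[np.ndarray, np.ndarray]:
    """Min-cost matching allowing unmatched rows/columns at ``penalty`` each.

    ``costs[i, j]`` is the cost of matching active i to detection j, with
    ``_BIG`` marking forbidden pairs.  Returns the matched (row, col) pairs.
    """
    na, nd = costs.shape
    size = na + nd
    a = np.full((size, size), _BIG)
    a[:na, :nd] = costs
    a[:na, nd:] = np.where(np.eye(na, dtype=bool), penalty, _BIG)
    a[na:, :nd] = np.where(np.eye(nd, dtype=bool), penalty, _BIG)
    # dummies may pair with dummies for free
    a[na:, nd:] = 0.0
    rows, cols = linear_sum_assignment(a)
    keep = (rows < na) & (cols < nd) & (a[rows, cols] < _BIG / 2)
    return rows[keep], cols[keep]


def link(detections: list[Detection], params: LinkParams | None = None) -> list[Trajectory]:
    """Assemble detections (sorted by frame) into trajectories.

    Particle ids are assigned in trajectory-creation order: by start frame,
    then by (y, x) of the founding detection, so output is deterministic.
    """
    params = params or LinkParams()
    if not detections:
        return []
    frames_of = np.array([d.frame for d in detections])
    if np.any(np.diff(frames_of) < 0):
        raise ValueError("detections must be sorted by frame")

    by_frame: dict[int, list[Detection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)

    first, last = int(frames_of[0]), int(frames_of[-1])
    active: list[_Active] = []
    finished: list[_Active] = []
    next_id = 0

    for f in range(first, last + 1):
        dets = sorted(by_frame.get(f, []), key=lambda d: (d.y_px, d.x_px))
        nd = len(dets)
        na = len(active)
        matched_active = np.zeros(na, dtype=bool)
        matched_det = np.zeros(nd, dtype=bool)

        if na and nd:
            ax = np.array([a.x for a in active])
            ay = np.array([a.y for a in active])
            gap = np.array([f - a.last_frame for a in active], dtype=float)
            dx = np.array([d.x_px for d in dets])
            dy = np.array([d.y_px for d in dets])
            dist = np.hypot(ax[:, None] - dx[None, :], ay[:, None] - dy[None, :])
            allowed = dist <= params.search_range_px * gap[:, None]

            # connected subnets over the bipartite candidate graph
            parent = list(range(na + nd))

            def find(i: int) -> int:
                while parent[i] != i:
                    parent[i] = parent[parent[i]]
                    i = parent[i]
                return i

            for i in range(na):
                for j in range(nd):
                    if allowed[i, j]:
                        ri, rj = find(i), find(na + j)
                        if ri != rj:
                            parent[ri] = rj

            comps: dict[int, tuple[list[int], list[int]]] = {}
            for i in range(na):
                comps.setdefault(find(i), ([], []))[0].append(i)
            for j in range(nd):
                comps.setdefault(find(na + j), ([], []))[1].append(j)

            penalty = params.search_range_px**2
            for ais, djs in comps.values():
                if not ais or not djs:
                    continue
                if max(len(ais), len(djs)) > params.max_subnet_size:
                    raise SubnetOversizeError(
                        f"subnet of {len(ais)} particles x {len(djs)} detections at frame {f} "
                        f"exceeds max_subnet_size={params.max_subnet_size}; reduce search_range_px"
                    )
                sub = np.where(allowed[np.ix_(ais, djs)], dist[np.ix_(ais, djs)] ** 2, _BIG)
                ri, rj = _solve_subnet(sub, penalty)
                for i, j in zip(ri, rj):
                    ai, dj = ais[i], djs[j]
                    d = dets[dj]
                    active[ai].points.append(d)
                    active[ai].x, active[ai].y = d.x_px, d.y_px
                    active[ai].last_frame = f
                    matched_active[ai] = True
                    matched_det[dj] = True

        # unmatched actives: age out when the gap exceeds the memory
        survivors: list[_Active] = []
        for i, a in enumerate(active):
            if matched_active[i]:
                survivors.append(a)
            elif f - a.last_frame >= params.memory_frames + 1:
                finished.append(a)
            else:
                survivors.append(a)
        active = survivors

        # unmatched detections found new trajectories, in (y, x) order
        for j, d in enumerate(dets):
            if not matched_det[j]:
                a = _Active(particle_id=next_id, x=d.x_px, y=d.y_px, last_frame=f, points=[d])
                next_id += 1
                active.append(a)

    finished.extend(active)
    finished.sort(key=lambda a: a.particle_id)
    out = []
    for a in finished:
        pts = a.points
        out.append(
            Trajectory(
                particle_id=a.particle_id,
                frames=np.array([p.frame for p in pts], dtype=np.int64),
                t_s=np.array([p.t_s for p in pts], dtype=np.float64),
                x_px=np.array([p.x_px for p in pts], dtype=np.float64),
                y_px=np.array([p.y_px for p in pts], dtype=np.float64),
                mass=np.array([p.mass for p in pts], dtype=np.float64),
            )
        )
    return out


@dataclass
class LinkScore:
    """Purity/coverage of linked trajectories against simulation truth."""

    purity: np.ndarray  # per trajectory: majority-truth-identity fraction
    coverage: np.ndarray  # per swimmer: fraction of frames matched
    mean_purity: float
    mean_coverage: float
    n_trajectories: int
    n_swimmers: int


def link_ground_truth_score(
    trajectories: list[Trajectory], truth, um_per_px: float, match_radius_px: float = 5.0
) -> LinkScore:
    """Score trajectories against ground truth by nearest-swimmer matching.

    Each trajectory point is matched to the nearest swimmer (within
    ``match_radius_px``) at that frame; a trajectory's purity is the
    fraction of its points voting for its majority swimmer, and a swimmer's
    coverage is the fraction of frames at which some trajectory point
    matched it.
    """
    if not trajectories or truth.n_swimmers == 0:
        return LinkScore(np.array([]), np.array([]), float("nan"), float("nan"), 0, getattr(truth, "n_swimmers", 0))

    tx = truth.x_um / um_per_px
    ty = truth.y_um / um_per_px
    purities = []
    covered = np.zeros((truth.n_swimmers, truth.n_frames), dtype=bool)
    for traj in trajectories:
        votes = []
        for k in range(traj.n_points):
            f = int(traj.frames[k])
            if not (0 <= f < truth.n_frames):
                continue
            d = np.hypot(tx[:, f] - traj.x_px[k], ty[:, f] - traj.y_px[k])
            s = int(np.argmin(d))
            if d[s] <= match_radius_px:
                votes.append(s)
                covered[s, f] = True
        if votes:
            counts = np.bincount(votes)
            purities.append(counts.max() / len(votes))
        else:
            purities.append(0.0)
    purity = np.array(purities)
    coverage = covered.mean(axis=1)
    return LinkScore(
        purity=purity,
        coverage=coverage,
        mean_purity=float(purity.mean()),
        mean_coverage=float(coverage.mean()),
        n_trajectories=len(trajectories),
        n_swimmers=truth.n_swimmers,
    )


def trajectories_to_dataframe(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Long-format table: particle_id, frame, t_s, x_px, y_px, mass."""
    if not trajectories:
        return pd.DataFrame(columns=["particle_id", "frame", "t_s", "x_px", "y_px", "mass"])
    parts = [
        pd.DataFrame(
            {
                "particle_id": t.particle_id,
                "frame": t.frames,
                "t_s": t.t_s,
                "x_px": t.x_px,
                "y_px": t.y_px,
                "mass": t.mass,
            }
        )
        for t in trajectories
    ]
    return pd.concat(parts, ignore_index=True)


def trajectories_from_dataframe(df: pd.DataFrame) -> list[Trajectory]:
    out = []
    for pid, g in df.groupby("particle_id", sort=True):
        g = g.sort_values("frame")
        out.append(
            Trajectory(
                particle_id=int(pid),
                frames=g["frame"].to_numpy(dtype=np.int64),
                t_s=g["t_s"].to_numpy(dtype=np.float64),
                x_px=g["x_px"].to_numpy(dtype=np.float64),
                y_px=g["y_px"].to_numpy(dtype=np.float64),
                mass=g["mass"].to_numpy(dtype=np.float64),
            )
        )
    return out
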