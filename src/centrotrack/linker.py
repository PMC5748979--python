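"""Trajectory assembly by anchor-frame propagation and gated assignment.

Spots are detected reliably only at sparse *anchor* frames (manual clicks in
the original workflow, seed files or auto-detection here).  Every other frame
borrows its search position from the adjacent frame on the path toward its
nearest anchor: with anchors at t1 and t6, t2 is searched around the spots of
t1, t3 around t2, while t4 — closer to t6 — is searched around t5, itself
seeded from t6.  Associations use a spherical gate of radius
r = 2 * dt * v_avg (1.6 µm at dt = 40 s, v_avg = 0.02 µm/s) and a globally
optimal one-to-one assignment per step, so the result does not depend on the
order detections are listed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from centrotrack.spots import SpotObservation

__all__ = ["PropagationPlan", "Trajectory", "mask_radius", "build_plan", "link"]

DEFAULT_MEAN_SPEED = 0.02  # µm/s, mean absolute centrosome speed


def mask_radius(frame_interval_s: float, mean_speed_um_s: float) -> float:
    """Spherical search-gate radius r = 2 * dt * v_avg (µm).

    Twice the expected per-frame displacement: at dt = 40 s and
    v_avg = 0.02 µm/s this gives the 1.6 µm gate.
    """
    if frame_interval_s <= 0 or mean_speed_um_s <= 0:
        raise ValueError("frame interval and mean speed must be > 0")
    return 2.0 * frame_interval_s * mean_speed_um_s


@dataclass
class PropagationPlan:
    """Which frame seeds the spot search at each non-anchor frame."""

    anchor_frames: list[int]
    source_of: dict[int, int]          # frame -> adjacent frame it is seeded from
    direction_of: dict[int, str]       # frame -> "forward" | "backward" | "anchor"
    n_frames: int

    def chain_to_anchor(self, frame: int) -> list[int]:
        """Frames visited following sources from ``frame`` to its anchor."""
        chain = [frame]
        while chain[-1] not in self.anchor_frames:
            chain.append(self.source_of[chain[-1]])
            if len(chain) > self.n_frames:
                raise RuntimeError("propagation plan does not terminate")
        return chain

    def processing_order(self) -> list[int]:
        """Frames ordered so every frame appears after its source."""
        order = list(self.anchor_frames)
        seen = set(order)
        remaining = [f for f in range(self.n_frames) if f not in seen]
        remaining.sort(key=lambda f: len(self.chain_to_anchor(f)))
        return order + remaining


@dataclass
class Trajectory:
    """Frame-ordered observations of one centrosome."""

    centrosome_id: int
    observations: list[SpotObservation] = field(default_factory=list)
    gaps: list[int] = field(default_factory=list)   # frames filled by interpolation

    @property
    def frames(self) -> np.ndarray:
        return np.array([o.frame for o in self.observations], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([o.center for o in self.observations])

    def position_at(self, frame: int) -> np.ndarray | None:
        for o in self.observations:
            if o.frame == frame:
                return o.center
        return None


def build_plan(anchor_frames, n_frames: int) -> PropagationPlan:
    """Assign every non-anchor frame to its nearest anchor (ties to the
    earlier anchor) and chain it frame-by-frame toward that anchor."""
    anchors = list(anchor_frames)
    if not anchors:
        raise ValueError("at least one anchor frame is required")
    if anchors != sorted(anchors) or len(set(anchors)) != len(anchors):
        raise ValueError("anchor frames must be strictly increasing")
    if anchors[0] < 0 or anchors[-1] >= n_frames:
        raise ValueError("anchor frames out of range")
    source_of: dict[int, int] = {}
    direction_of: dict[int, str] = {a: "anchor" for a in anchors}
    arr = np.array(anchors)
    for f in range(n_frames):
        if f in direction_of:
            continue
        dist = np.abs(arr - f)
        nearest = int(arr[int(np.argmin(dist))])   # argmin ties -> earlier anchor
        if nearest > f:
            source_of[f] = f + 1                    # propagate backward from anchor
            direction_of[f] = "backward"
        else:
            source_of[f] = f - 1
            direction_of[f] = "forward"
    return PropagationPlan(anchor_frames=anchors, source_of=source_of,
                           direction_of=direction_of, n_frames=n_frames)


def _assign(sources: np.ndarray, targets: np.ndarray, gate: float):
    """Globally optimal one-to-one matching under the gate.

    Returns list of (source_idx, target_idx) pairs with distance <= gate.
    """
    if len(sources) == 0 or len(targets) == 0:
        return []
    cost = np.linalg.norm(sources[:, None, :] - targets[None, :, :], axis=2)
    big = 1e6
    padded = np.where(cost <= gate, cost, big)
    rows, cols = linear_sum_assignment(padded)
    return [(int(r), int(c)) for r, c in zip(rows, cols)
            if cost[r, c] <= gate]


def _link_block(frames: list[int], anchor: int,
                spots_by_frame, plan: PropagationPlan, radius_um: float):
    """Track identities within one anchor's contiguous block of frames.

    Returns (observations_per_track, position_per_track_per_frame).
    """
    obs_a = spots_by_frame.get(anchor, [])
    track_obs = [[o] for o in obs_a]
    pos_at = [{anchor: o.center} for o in obs_a]
    for frame in sorted(frames, key=lambda f: abs(f - anchor)):
        if frame == anchor:
            continue
        src = plan.source_of[frame]
        obs = spots_by_frame.get(frame, [])
        centers = np.array([o.center for o in obs]).reshape(len(obs), 3)
        src_pos = np.array([p[src] for p in pos_at]).reshape(len(pos_at), 3)
        matches = _assign(src_pos, centers, radius_um)
        matched_src = {m[0] for m in matches}
        for si, ti in matches:
            track_obs[si].append(obs[ti])
            pos_at[si][frame] = obs[ti].center
        for si in range(len(pos_at)):
            if si not in matched_src:
                # carry the position so the search can continue past a miss
                pos_at[si][frame] = src_pos[si]
    return track_obs, pos_at


def link(spots_by_frame: dict[int, list[SpotObservation]],
         plan: PropagationPlan, radius_um: float,
         max_gap: int = 2) -> list[Trajectory]:
    """Assemble trajectories from per-frame detections along the plan.

    Each anchor owns the contiguous block of frames nearest to it; within a
    block, detections are matched step by step (in plan order) to the tracked
    position at the source frame by a globally optimal one-to-one assignment
    under the gate.  Consecutive blocks are stitched at their boundary by the
    same gated assignment, so identities persist across anchors.  A track
    missing a detection carries its last position; gaps of up to ``max_gap``
    frames are filled by linear interpolation between flanking observations,
    longer gaps terminate the track.
    """
    anchors = plan.anchor_frames
    owner: dict[int, int] = {}
    for f in range(plan.n_frames):
        owner[f] = plan.chain_to_anchor(f)[-1]
    blocks = [(a, [f for f in range(plan.n_frames) if owner[f] == a])
              for a in anchors]

    global_obs: list[list[SpotObservation]] = []
    global_pos: list[dict[int, np.ndarray]] = []
    for bi, (anchor, frames) in enumerate(blocks):
        t_obs, t_pos = _link_block(frames, anchor, spots_by_frame, plan,
                                   radius_um)
        if bi == 0:
            global_obs, global_pos = t_obs, t_pos
            continue
        # stitch: previous block's last frame vs this block's first frame
        cf = min(frames)
        pf = cf - 1
        prev_pos = np.array([p.get(pf, p[max(p)]) for p in global_pos]
                            ).reshape(len(global_pos), 3)
        cur_pos = np.array([p[cf] for p in t_pos]).reshape(len(t_pos), 3)
        matches = _assign(prev_pos, cur_pos, radius_um)
        matched_cur = set()
        for gi, ci in matches:
            global_obs[gi].extend(t_obs[ci])
            global_pos[gi].update(t_pos[ci])
            matched_cur.add(ci)
        for ci in range(len(t_obs)):
            if ci not in matched_cur:   # spot appearing only in later blocks
                global_obs.append(t_obs[ci])
                global_pos.append(t_pos[ci])

    tracks = []
    for tid, obs in enumerate(global_obs):
        t = Trajectory(centrosome_id=tid,
                       observations=sorted(obs, key=lambda o: o.frame))
        _fill_gaps(t, max_gap)
        tracks.append(t)
    return tracks


def _fill_gaps(track: Trajectory, max_gap: int) -> None:
    """Linear interpolation across gaps of at most ``max_gap`` frames;
    a longer gap truncates the track at its first run of observations."""
    obs = track.observations
    if len(obs) < 2:
        return
    filled: list[SpotObservation] = [obs[0]]
    for prev, nxt in zip(obs, obs[1:]):
        gap = nxt.frame - prev.frame - 1
        if gap == 0:
            filled.append(nxt)
            continue
        if gap > max_gap:
            break                         # terminate at the long gap
        for g in range(1, gap + 1):
            f = prev.frame + g
            w = g / (gap + 1)
            center = (1 - w) * prev.center + w * nxt.center
            filled.append(SpotObservation(
                frame=f, center=center,
                amplitude=(1 - w) * prev.amplitude + w * nxt.amplitude,
                sigma=prev.sigma, fit_residual=np.nan, source="interpolated"))
            track.gaps.append(f)
        filled.append(nxt)
    track.observations = filled
    track.gaps = sorted(set(track.gaps) & {o.frame for o in filled})
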