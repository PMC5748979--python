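"""Clustering kinematics of centrosome pairs.

From tracked trajectories this module derives the quantities that expose the
biphasic clustering mechanism: the pair separation d(t), the completion time
at which separation stabilizes at a clustered value, the change point
splitting the record into a confined search-and-capture phase and a directed
motorized phase (with its speed and onset separation), mean-square
displacement of the separation, population statistics after aligning pairs at
a common event, and pooled separation histograms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from centrotrack.linker import Trajectory

__all__ = [
    "SeparationSeries",
    "PhaseSegmentation",
    "MsdCurve",
    "AlignedPopulationStats",
    "separation_series",
    "detect_completion",
    "segment_phases",
    "msd",
    "align_population",
    "classify_pairs",
    "phase_histogram",
]

# operational defaults for "separation stabilized"
D_CLUSTERED_UM = 2.0
STABILITY_WINDOW = 5
STABILITY_SD_UM = 0.3


@dataclass
class SeparationSeries:
    """Pair separation d(t) on a uniform time grid."""

    pair_id: str
    time_s: np.ndarray
    d: np.ndarray
    condition_label: str = ""
    anaphase_onset_frame: int | None = None
    interpolated: np.ndarray | None = None   # bool per frame
    frame0: int = 0                          # frame index of the first sample

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        if self.time_s.shape != self.d.shape:
            raise ValueError("time and d must have equal length")
        if np.any(self.d < 0):
            raise ValueError("separation must be non-negative")
        steps = np.diff(self.time_s)
        if len(steps) and (np.any(steps <= 0)
                           or not np.allclose(steps, steps[0])):
            raise ValueError("time must be strictly increasing with constant step")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    @property
    def n(self) -> int:
        return self.d.size


@dataclass
class PhaseSegmentation:
    """Biphasic decomposition of one clustering pair."""

    pair_id: str
    completion_frame: int | None
    motorized_onset_frame: int | None
    search_interval: tuple[int, int] | None      # [start, end] inclusive, frames
    motorized_interval: tuple[int, int] | None
    motorized_speed_um_s: float | None
    onset_separation_um: float | None
    sse: float = np.nan


@dataclass
class MsdCurve:
    lag_s: np.ndarray
    msd: np.ndarray
    n_contributing: np.ndarray


@dataclass
class AlignedPopulationStats:
    aligned_time_s: np.ndarray
    mean_d: np.ndarray
    sd_d: np.ndarray          # NaN where n < 2
    n: np.ndarray


def separation_series(traj_a: Trajectory, traj_b: Trajectory,
                      frame_interval_s: float,
                      pair_id: str = "pair",
                      condition_label: str = "",
                      anaphase_onset_frame: int | None = None) -> SeparationSeries:
    """3D Euclidean separation of two trajectories on their common frames."""
    fa = {o.frame: o for o in traj_a.observations}
    fb = {o.frame: o for o in traj_b.observations}
    common = sorted(set(fa) & set(fb))
    if len(common) < 3:
        raise ValueError("trajectories share fewer than 3 common frames")
    if np.any(np.diff(common) != 1):
        # restrict to the longest contiguous run so the time step is constant
        runs, start = [], 0
        for i in range(1, len(common)):
            if common[i] != common[i - 1] + 1:
                runs.append(common[start:i])
                start = i
        runs.append(common[start:])
        common = max(runs, key=len)
        if len(common) < 3:
            raise ValueError("trajectories share fewer than 3 contiguous frames")
    d = np.array([np.linalg.norm(fa[f].center - fb[f].center) for f in common])
    interp = np.array([fa[f].source == "interpolated"
                       or fb[f].source == "interpolated" for f in common])
    return SeparationSeries(
        pair_id=pair_id,
        time_s=np.array(common, dtype=float) * frame_interval_s,
        d=d, condition_label=condition_label,
        anaphase_onset_frame=anaphase_onset_frame,
        interpolated=interp, frame0=common[0])


def detect_completion(series: SeparationSeries,
                      d_clustered: float = D_CLUSTERED_UM,
                      stability_window: int = STABILITY_WINDOW,
                      stability_sd: float = STABILITY_SD_UM) -> int | None:
    """Earliest frame from which separation stays low and stable.

    Completion is the first index t_c such that d(t) <= d_clustered for every
    t >= t_c and every length-``stability_window`` window within [t_c, end)
    has SD <= stability_sd.  Returns None when separation never stabilizes.
    The returned index is relative to the start of the series (add
    ``series.frame0`` for absolute frames).
    """
    d = series.d
    n = d.size
    if n < stability_window:
        warnings.warn("series shorter than stability window", stacklevel=2)
        return None
    below = d <= d_clustered
    # earliest index from which all remaining samples are below threshold
    idx_above = np.nonzero(~below)[0]
    first_ok = int(idx_above[-1]) + 1 if idx_above.size else 0
    for t_c in range(first_ok, n - stability_window + 1):
        tail = d[t_c:]
        sds = _rolling_sd(tail, stability_window)
        if np.all(sds <= stability_sd):
            return t_c
    return None


def _rolling_sd(x: np.ndarray, w: int) -> np.ndarray:
    if x.size < w:
        return np.array([np.std(x)])
    windows = np.lib.stride_tricks.sliding_window_view(x, w)
    return windows.std(axis=1)


def segment_phases(series: SeparationSeries, completion: int,
                   search_start: int = 0) -> PhaseSegmentation:
    """Two-piece plateau + linear-descent change-point fit up to completion.

    The model is a constant plateau through the change point followed by a
    linear descent that reaches the observed d(completion): with knot k and
    N = completion, f(t) = d(N) + m * (t - N) for t >= k and f(t) = f(k) for
    t < k.  The single slope m is fit by least squares for every candidate
    knot over [search_start, completion]; the knot minimizing total squared
    error wins.  The reported onset is the first descending frame b = k + 1,
    the motorized speed is |m| per second, and the onset separation is the
    observed d at that change-point frame.  A non-negative fitted slope
    rejects the segmentation (pair unsegmentable).
    """
    d = series.d[search_start:completion + 1]
    n = d.size
    if n < 4:
        raise ValueError("too few frames before completion to segment")
    t = np.arange(n, dtype=float)
    N = n - 1
    y = d - d[N]
    best = None
    for k in range(0, n - 2):
        x = np.where(t < k, float(k - N), t - N)
        m_hat = float(x @ y) / float(x @ x)
        resid = y - m_hat * x
        sse = float(resid @ resid)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, k + 1, m_hat)
    sse, b, m = best
    if m >= 0:
        return PhaseSegmentation(
            pair_id=series.pair_id, completion_frame=completion,
            motorized_onset_frame=None, search_interval=None,
            motorized_interval=None, motorized_speed_um_s=None,
            onset_separation_um=None, sse=sse)
    onset = search_start + b
    return PhaseSegmentation(
        pair_id=series.pair_id,
        completion_frame=completion,
        motorized_onset_frame=onset,
        search_interval=(search_start, onset - 1),
        motorized_interval=(onset, completion),
        motorized_speed_um_s=float(-m) / series.dt,
        onset_separation_um=float(series.d[onset]),
        sse=sse)


def msd(series_set, phase: str = "all", max_lag_s: float | None = None,
        segmentations=None) -> MsdCurve:
    """Time-averaged mean-square displacement of the separation.

    MSD(tau) averages (d(t+tau) - d(t))^2 over all start times t and all
    series.  With phase="search", both t and t+tau are restricted to each
    series' search-and-capture interval (requires ``segmentations`` aligned
    with ``series_set``; series without a motorized onset contribute their
    whole record).
    """
    series_set = list(series_set)
    if not series_set:
        raise ValueError("need at least one series")
    dt = series_set[0].dt
    max_lag = (int(round(max_lag_s / dt)) if max_lag_s is not None
               else max(s.n for s in series_set) - 1)
    sums = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1, dtype=int)
    for i, s in enumerate(series_set):
        d = s.d
        lo, hi = 0, s.n - 1
        if phase == "search" and segmentations is not None:
            seg = segmentations[i]
            if seg is not None and seg.motorized_onset_frame is not None:
                hi = seg.motorized_onset_frame - 1 - s.frame0
        d = d[lo:hi + 1]
        for k in range(0, min(max_lag, d.size - 1) + 1):
            diffs = d[k:] - d[:d.size - k]
            sums[k] += np.sum(diffs ** 2)
            counts[k] += diffs.size
    valid = counts > 0
    return MsdCurve(lag_s=np.nonzero(valid)[0] * dt,
                    msd=sums[valid] / counts[valid],
                    n_contributing=counts[valid])


def align_population(series_set, event: str = "anaphase_onset",
                     events: dict | None = None) -> AlignedPopulationStats:
    """Cross-pair mean and SD of d after aligning each series at an event.

    ``event`` is "anaphase_onset" (uses each series' annotation) or
    "completion" (requires ``events`` mapping pair_id -> absolute frame).
    Series missing the event are excluded with a warning.  Aligned time 0 is
    the event frame; at times contributed by a single pair the SD is NaN.
    """
    aligned: list[tuple[np.ndarray, np.ndarray]] = []
    for s in series_set:
        if event == "anaphase_onset":
            ev = s.anaphase_onset_frame
        else:
            ev = (events or {}).get(s.pair_id)
        if ev is None:
            warnings.warn(f"series {s.pair_id} lacks event {event!r}; excluded",
                          stacklevel=2)
            continue
        rel = np.arange(s.frame0, s.frame0 + s.n) - ev
        aligned.append((rel, s.d))
    if not aligned:
        raise ValueError("no series carries the alignment event")
    lo = min(int(r[0]) for r, _ in aligned)
    hi = max(int(r[-1]) for r, _ in aligned)
    times = np.arange(lo, hi + 1)
    mean = np.full(times.size, np.nan)
    sd = np.full(times.size, np.nan)
    n = np.zeros(times.size, dtype=int)
    for j, rel_t in enumerate(times):
        vals = [d[np.nonzero(r == rel_t)[0][0]]
                for r, d in aligned if rel_t in r]
        if vals:
            n[j] = len(vals)
            mean[j] = np.mean(vals)
            if len(vals) >= 2:
                sd[j] = np.std(vals, ddof=1)
    keep = n >= 1
    dt = series_set[0].dt
    return AlignedPopulationStats(aligned_time_s=times[keep] * dt,
                                  mean_d=mean[keep], sd_d=sd[keep], n=n[keep])


def classify_pairs(series_set, d_clustered: float = D_CLUSTERED_UM,
                   stability_window: int = STABILITY_WINDOW,
                   stability_sd: float = STABILITY_SD_UM):
    """Label each pair clustered/failed by completion detection.

    Returns (labels, summary): labels maps pair_id to "clustered" or
    "failed"; summary counts both classes and, where anaphase annotations
    exist, the fraction of clustered pairs completing before anaphase onset.
    """
    labels: dict[str, str] = {}
    completions: dict[str, int | None] = {}
    before_anaphase = 0
    annotated = 0
    for s in series_set:
        c = detect_completion(s, d_clustered, stability_window, stability_sd)
        completions[s.pair_id] = c
        labels[s.pair_id] = "clustered" if c is not None else "failed"
        if c is not None and s.anaphase_onset_frame is not None:
            annotated += 1
            if c + s.frame0 <= s.anaphase_onset_frame:
                before_anaphase += 1
    n_clustered = sum(1 for v in labels.values() if v == "clustered")
    summary = {
        "n_clustered": n_clustered,
        "n_failed": len(labels) - n_clustered,
        "fraction_clustered": n_clustered / len(labels) if labels else np.nan,
        "fraction_before_anaphase": (before_anaphase / annotated
                                     if annotated else np.nan),
        "completions": completions,
    }
    return labels, summary


def phase_histogram(series_set, segmentations=None, bin_width: float = 0.5,
                    n_boot: int = 1000, seed: int = 0):
    """Pooled histogram of separation during the search-and-capture phase.

    Clustered pairs contribute frames before their motorized onset (their
    segmentation must be supplied); failed pairs contribute their whole
    pre-anaphase span.  Returns (bin_edges, counts, median, sem_median) with
    the SEM of the median from a seeded bootstrap.
    """
    pool: list[np.ndarray] = []
    for i, s in enumerate(series_set):
        seg = segmentations[i] if segmentations is not None else None
        if seg is not None and seg.motorized_onset_frame is not None:
            hi = seg.motorized_onset_frame - s.frame0
            pool.append(s.d[:hi])
        else:
            hi = s.n
            if s.anaphase_onset_frame is not None:
                hi = min(hi, max(0, s.anaphase_onset_frame - s.frame0))
            pool.append(s.d[:hi])
    samples = np.concatenate(pool) if pool else np.array([])
    if samples.size == 0:
        raise ValueError("empty separation pool")
    edges = np.arange(0.0, samples.max() + bin_width, bin_width)
    if edges[-1] <= samples.max():
        edges = np.append(edges, edges[-1] + bin_width)
    counts, _ = np.histogram(samples, bins=edges)
    median = float(np.median(samples))
    rng = np.random.default_rng(seed)
    boots = np.median(
        rng.choice(samples, size=(n_boot, samples.size), replace=True), axis=1)
    return edges, counts, median, float(np.std(boots, ddof=1))
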