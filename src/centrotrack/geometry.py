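"""Spindle-pole geometry and clustering-efficiency tabulation.

In a tripolar metaphase the smallest of the three angles subtended at the
pole centroid measures how close the two nearest poles are to merging into a
single clustered pole.  Populations of these angles are summarized as rose
(angular frequency) histograms.  Clustering efficiency is the fraction of
divisions with supernumerary centrioles (>4) that are nevertheless bipolar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "TripolarSpindle",
    "EfficiencyCount",
    "smallest_pole_angle",
    "pole_angles",
    "rose_histogram",
    "clustering_efficiency",
]


@dataclass
class TripolarSpindle:
    """Three spindle-pole coordinates (µm, 2D or 3D) of one cell."""

    cell_id: str
    poles: np.ndarray
    condition_label: str = ""
    truth_angle: float | None = None    # set by the simulator

    def __post_init__(self) -> None:
        self.poles = np.asarray(self.poles, dtype=float)
        if self.poles.shape not in ((3, 2), (3, 3)):
            raise ValueError("poles must be three 2D or 3D coordinates")
        v1 = self.poles[1] - self.poles[0]
        v2 = self.poles[2] - self.poles[0]
        if self.poles.shape[1] == 2:
            cross = abs(v1[0] * v2[1] - v1[1] * v2[0])
        else:
            cross = np.linalg.norm(np.cross(v1, v2))
        if cross <= 1e-6:
            raise ValueError("poles are collinear or coincident")


@dataclass
class EfficiencyCount:
    condition_label: str
    stage: str                      # metaphase | telophase | cytokinesis
    n_bipolar_clustered: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_bipolar_clustered <= self.n_total):
            raise ValueError("require 0 <= n_bipolar_clustered <= n_total")


def pole_angles(spindle: TripolarSpindle) -> np.ndarray:
    """The three angles (degrees) subtended at the pole centroid.

    The centroid lies inside the pole triangle (and in its plane for 3D
    input), so the three angles partition the full turn and sum to 360.
    """
    centroid = spindle.poles.mean(axis=0)
    v = spindle.poles - centroid
    angles = []
    for i, j in ((0, 1), (1, 2), (2, 0)):
        cosang = np.dot(v[i], v[j]) / (np.linalg.norm(v[i]) * np.linalg.norm(v[j]))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return np.array(angles)


def smallest_pole_angle(spindle: TripolarSpindle) -> float:
    """Smallest centroid-subtended inter-pole angle in degrees (<= 120)."""
    return float(pole_angles(spindle).min())


def rose_histogram(angles, bin_width: float = 10.0):
    """Right-open angular bins from 0; returns (bin_edges, counts, mean).

    Angles must lie in (0, 120] — the range attainable by the smallest of
    three angles summing to 360.
    """
    angles = np.asarray(angles, dtype=float)
    bad = (angles <= 0) | (angles > 120)
    if bad.any():
        raise ValueError(f"angle out of (0, 120]: {angles[bad][0]:g} degrees")
    n_bins = int(np.ceil(120.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    # right-open bins [k*w, (k+1)*w); the top edge 120 closes into the last bin
    idx = np.minimum((angles // bin_width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return edges, counts, float(angles.mean())


def clustering_efficiency(counts: EfficiencyCount,
                          alpha: float = 0.05):
    """Clustered fraction with a Wilson score confidence interval.

    Returns (fraction, (ci_low, ci_high)).
    """
    if counts.n_total == 0:
        raise ValueError("n_total must be > 0")
    frac = counts.n_bipolar_clustered / counts.n_total
    lo, hi = proportion_confint(counts.n_bipolar_clustered, counts.n_total,
                                alpha=alpha, method="wilson")
    return frac, (float(lo), float(hi))
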