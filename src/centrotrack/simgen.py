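"""Synthetic ground truth for every stage of the pipeline.

The generator emulates the study conditions of the clustering experiments:
centrosome pairs imaged over 35 z-slices (500 nm spacing) every 40 s, with a
confined stochastic search-and-capture phase (stationary SD ~1-2 µm depending
on condition), a motorized phase that initiates once separation falls to
~7.5 µm and closes the pair over ~15 min, and non-clustering pairs fluctuating
around ~11.5 µm.  AFM force curves follow the conical Sneddon law with a flat
pre-contact baseline.  All outputs carry their ground truth so downstream
detection, linking, segmentation and fitting can be scored against it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from centrotrack.spots import ImageStack

__all__ = [
    "MotionParams",
    "OpticsParams",
    "SyntheticTruth",
    "AfmSimParams",
    "simulate_pair",
    "render_stack",
    "simulate_tripolar",
    "simulate_force_curve",
]


@dataclass(frozen=True)
class MotionParams:
    """Parameters of one centrosome pair's separation dynamics.

    Lengths in µm, times in s.  Defaults reproduce the observed magnitudes:
    motorized phase initiating at 7.5 µm and lasting 900 s (15 min), frames
    every 40 s, non-clustering baseline 11.5 µm with condition-dependent
    search-phase SD (2 µm wild-type-like, 1 µm E-cadherin-knockout-like).
    """

    mean_separation_search: float = 11.5
    sd_search: float = 2.0
    reversion_time: float = 200.0
    onset_separation: float = 7.5
    motorized_duration: float = 900.0
    final_separation: float = 1.5
    frame_interval: float = 40.0
    n_frames: int = 90
    cluster: bool = True
    seed: int = 0
    # anaphase follows completion by this many frames for clustering pairs;
    # for non-clustering pairs it is placed this many frames before the end.
    anaphase_offset_frames: int = 2

    def validate(self) -> None:
        for name in ("mean_separation_search", "reversion_time",
                     "onset_separation", "motorized_duration",
                     "final_separation", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sd_search < 0:
            raise ValueError("sd_search must be >= 0")
        if not (self.final_separation < self.onset_separation
                <= self.mean_separation_search):
            raise ValueError(
                "require final_separation < onset_separation <= mean_separation_search")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def motorized_steps(self) -> int:
        """Number of frame intervals the directed descent occupies."""
        return int(math.ceil(self.motorized_duration / self.frame_interval))


@dataclass(frozen=True)
class OpticsParams:
    """Acquisition model: voxel calibration, PSF widths and noise.

    n_z=35 / z_spacing=0.5 µm match the acquisition (35 z-slices at 500 nm);
    pixel 0.13 µm corresponds to a 100x/1.45 NA objective with 2x2 binning.
    """

    pixel_size_xy: float = 0.13
    z_spacing: float = 0.5
    n_z: int = 35
    n_y: int = 128
    n_x: int = 128
    psf_sigma_xy: float = 0.11
    psf_sigma_z: float = 0.35
    spot_amplitude: float = 500.0
    background: float = 10.0
    noise_model: str = "poisson"          # "none" | "poisson" | "poisson+gaussian"
    read_noise_sd: float = 2.0            # only for poisson+gaussian
    seed: int = 0

    def validate(self) -> None:
        if self.n_z < 1 or self.n_y < 1 or self.n_x < 1:
            raise ValueError("stack dimensions must be >= 1")
        for name in ("pixel_size_xy", "z_spacing", "psf_sigma_xy", "psf_sigma_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.spot_amplitude <= 0:
            raise ValueError("spot_amplitude must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth twin of a tracked centrosome pair.

    positions: (n_frames, 2, 3) array of (x, y, z) in µm.
    separation: (n_frames,) pairwise distance d(t) in µm.
    """

    positions: np.ndarray
    separation: np.ndarray
    frame_interval: float
    completion_frame: int | None
    motorized_onset_frame: int | None
    anaphase_onset_frame: int
    params: MotionParams = field(repr=False, default=None)

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class AfmSimParams:
    """Forward model of one AFM approach curve on a cell.

    Defaults match the indentation protocol: 0.006 N/m nominal spring
    constant, 2.5 µm/s approach.  true_modulus in Pa; contact_point in µm of
    piezo travel; noise_sd in pN applied to force.
    """

    true_modulus: float = 1000.0
    poisson_ratio: float = 0.5
    tip_half_angle: float = 35.0
    contact_point: float = 2.0
    spring_constant: float = 0.006
    approach_speed: float = 2.5
    sample_spacing: float = 10.0        # nm of piezo travel between samples
    max_indentation: float = 1500.0     # nm
    noise_sd: float = 0.0               # pN on force
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise ValueError("poisson_ratio must be in [0, 0.5]")
        if not (0.0 < self.tip_half_angle < 90.0):
            raise ValueError("tip_half_angle must be in (0, 90) degrees")
        if self.max_indentation <= 0:
            raise ValueError("max_indentation must be > 0")
        if self.true_modulus <= 0 or self.spring_constant <= 0:
            raise ValueError("modulus and spring constant must be > 0")
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be > 0")
        if self.contact_point <= 0:
            raise ValueError("contact_point must be > 0")


# ---------------------------------------------------------------------------
# pair separation dynamics


def _separation_process(p: MotionParams, rng: np.random.Generator):
    """Simulate d(t) and return (d, motorized_onset, completion)."""
    n = p.n_frames
    d = np.empty(n)
    # discrete-time Ornstein-Uhlenbeck: stationary mean/SD are exactly
    # (mean_separation_search, sd_search); reflected at 0.
    a = math.exp(-p.frame_interval / p.reversion_time)
    innov_sd = p.sd_search * math.sqrt(max(0.0, 1.0 - a * a))
    mu = p.mean_separation_search
    d[0] = abs(mu + p.sd_search * rng.standard_normal())
    onset = None
    completion = None
    steps = p.motorized_steps
    t = 0
    while t < n - 1:
        if p.cluster and onset is None and d[t] <= p.onset_separation:
            onset = t
            break
        d[t + 1] = abs(mu + a * (d[t] - mu) + innov_sd * rng.standard_normal())
        t += 1
    if p.cluster and onset is None and d[n - 1] <= p.onset_separation:
        onset = n - 1
    if onset is not None:
        d_on = d[onset]
        per_step = (d_on - p.final_separation) / steps
        for k in range(1, steps + 1):
            idx = onset + k
            if idx >= n:
                break
            d[idx] = d_on - per_step * k
        if onset + steps < n:
            completion = onset + steps
            # post-completion jitter about the plateau, SD well under 0.1 µm
            for idx in range(completion + 1, n):
                d[idx] = abs(p.final_separation + 0.03 * rng.standard_normal())
        else:
            onset = None  # descent did not finish within the movie
    return d, onset, completion


def _embed_positions(d: np.ndarray, p: MotionParams, rng: np.random.Generator,
                     midpoint: np.ndarray) -> np.ndarray:
    """Place the pair symmetrically about a fixed midpoint on a slowly
    precessing axis so that pairwise distance equals d(t) exactly."""
    n = d.size
    # initial orientation in-plane: the z extent of the volume is the shallow
    # dimension, and the axis only drifts slowly out of plane
    theta0 = rng.uniform(0, 2 * np.pi)
    axis = np.array([np.cos(theta0), np.sin(theta0), 0.0])
    positions = np.empty((n, 2, 3))
    for t in range(n):
        positions[t, 0] = midpoint + 0.5 * d[t] * axis
        positions[t, 1] = midpoint - 0.5 * d[t] * axis
        # small random rotation per frame: ~2 deg in-plane, ~0.5 deg axial
        dphi = rng.normal(0.0, np.deg2rad(2.0))
        dpsi = rng.normal(0.0, np.deg2rad(0.5))
        c, s = np.cos(dphi), np.sin(dphi)
        axis = np.array([c * axis[0] - s * axis[1],
                         s * axis[0] + c * axis[1],
                         axis[2] + dpsi])
        axis /= np.linalg.norm(axis)
    return positions


def simulate_pair(params: MotionParams,
                  midpoint: np.ndarray | None = None) -> SyntheticTruth:
    """Simulate one centrosome pair with known biphasic ground truth.

    The separation d(t) follows a mean-reverting confined process (stationary
    mean ``mean_separation_search``, SD ``sd_search``, timescale
    ``reversion_time``) until the first frame at which d <= onset_separation
    while ``cluster`` is true; from the next frame it descends linearly to
    ``final_separation`` over ``motorized_duration`` and then fluctuates about
    the plateau.  Proximity alone is not sufficient for clustering: pairs with
    ``cluster=False`` never enter the motorized phase regardless of distance.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    d, onset, completion = _separation_process(params, rng)
    if midpoint is None:
        midpoint = np.array([8.32, 8.32, 8.75])  # center of the default volume
    midpoint = np.asarray(midpoint, dtype=float)
    positions = _embed_positions(d, params, rng, midpoint)
    if completion is not None:
        anaphase = min(params.n_frames - 1,
                       completion + params.anaphase_offset_frames)
    else:
        anaphase = max(0, params.n_frames - 1 - params.anaphase_offset_frames)
    if not params.cluster:
        onset = completion = None
    return SyntheticTruth(
        positions=positions,
        separation=d,
        frame_interval=params.frame_interval,
        completion_frame=completion,
        motorized_onset_frame=onset if completion is not None else None,
        anaphase_onset_frame=anaphase,
        params=params,
    )


# ---------------------------------------------------------------------------
# image formation


def render_stack(truth: SyntheticTruth, optics: OpticsParams) -> ImageStack:
    """Render the pair as anisotropic 3D Gaussian spots in a calibrated stack.

    Voxel centers sit at (i + 0.5) * spacing; each spot contributes
    ``spot_amplitude`` at its true position, decaying with the PSF sigmas, on
    a constant background.  Noise per ``noise_model``; deterministic per seed.
    """
    optics.validate()
    nt = truth.n_frames
    nz, ny, nx = optics.n_z, optics.n_y, optics.n_x
    extent = np.array([nx * optics.pixel_size_xy,
                       ny * optics.pixel_size_xy,
                       nz * optics.z_spacing])
    for t in range(nt):
        for c in range(truth.positions.shape[1]):
            pos = truth.positions[t, c]
            if np.any(pos < 0) or np.any(pos >= extent):
                raise ValueError(
                    f"position outside rendered volume: frame {t}, "
                    f"centrosome {c}, position {pos} µm, volume {extent} µm")
    xs = (np.arange(nx) + 0.5) * optics.pixel_size_xy
    ys = (np.arange(ny) + 0.5) * optics.pixel_size_xy
    zs = (np.arange(nz) + 0.5) * optics.z_spacing
    data = np.full((nt, nz, ny, nx), float(optics.background))
    two_sxy2 = 2.0 * optics.psf_sigma_xy ** 2
    two_sz2 = 2.0 * optics.psf_sigma_z ** 2
    for t in range(nt):
        for c in range(truth.positions.shape[1]):
            x0, y0, z0 = truth.positions[t, c]
            gx = np.exp(-((xs - x0) ** 2) / two_sxy2)
            gy = np.exp(-((ys - y0) ** 2) / two_sxy2)
            gz = np.exp(-((zs - z0) ** 2) / two_sz2)
            data[t] += optics.spot_amplitude * (
                gz[:, None, None] * gy[None, :, None] * gx[None, None, :])
    if optics.noise_model != "none":
        rng = np.random.default_rng(optics.seed)
        data = rng.poisson(data).astype(float)
        if optics.noise_model == "poisson+gaussian":
            data += rng.normal(0.0, optics.read_noise_sd, size=data.shape)
            data = np.clip(data, 0.0, None)
    return ImageStack(
        data=data,
        pixel_size_xy=optics.pixel_size_xy,
        z_spacing=optics.z_spacing,
        frame_interval=truth.frame_interval,
    )


# ---------------------------------------------------------------------------
# tripolar spindles


def _poles_for_angles(angles_deg: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Place three poles whose centroid-subtended angles are ``angles_deg``
    (summing to 360), randomly rotated/scaled/translated in the plane."""
    a1, a2, _ = np.deg2rad(angles_deg)
    dirs = np.stack([
        np.array([1.0, 0.0]),
        np.array([np.cos(a1), np.sin(a1)]),
        np.array([np.cos(a1 + a2), np.sin(a1 + a2)]),
    ])
    # radii r_i > 0 with sum r_i * dirs_i = 0 put the centroid at the origin
    r23 = np.linalg.solve(dirs[1:].T, -dirs[0])
    radii = np.array([1.0, r23[0], r23[1]])
    poles = radii[:, None] * dirs
    scale = rng.uniform(3.0, 6.0)       # µm, typical pole-centroid distances
    theta = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    offset = rng.uniform(5.0, 15.0, size=2)
    return poles @ rot.T * scale + offset


def simulate_tripolar(n: int, angle_mean: float, angle_sd: float,
                      seed: int = 0) -> list:
    """Simulate tripolar metaphase pole sets with known smallest angles.

    The smallest centroid-subtended angle of each spindle is drawn from a
    normal(angle_mean, angle_sd) truncated to (0, 120]; the remaining two
    angles split the rest of the turn unevenly at random.  Returns a list of
    :class:`centrotrack.geometry.TripolarSpindle` with ``truth_angle`` set.
    """
    from centrotrack.geometry import TripolarSpindle

    if not (0.0 < angle_mean <= 120.0):
        raise ValueError("angle_mean must be in (0, 120] degrees")
    if angle_sd < 0:
        raise ValueError("angle_sd must be >= 0")
    rng = np.random.default_rng(seed)
    spindles = []
    for i in range(n):
        while True:
            theta = angle_mean + angle_sd * rng.standard_normal()
            if 0.0 < theta <= 120.0:
                break
        rest = 360.0 - theta
        # the other two angles must each lie in [theta, 180): below 180
        # because the centroid of three non-collinear poles cannot sit on a
        # line joining two of them, and at least theta so theta is smallest
        lo = max(theta, rest - 180.0 + 1e-6)
        hi = min(180.0 - 1e-6, rest - theta)
        frac = rng.uniform(0.25, 0.75) if angle_sd > 0 else 0.5
        beta = lo + frac * (hi - lo)
        angles = np.array([theta, beta, rest - beta])
        poles = _poles_for_angles(angles, rng)
        spindles.append(TripolarSpindle(
            cell_id=f"sim{i:04d}", poles=poles,
            condition_label="simulated", truth_angle=float(theta)))
    return spindles


# ---------------------------------------------------------------------------
# AFM force curves


def sneddon_force(delta_m: np.ndarray, modulus_pa: float, poisson_ratio: float,
                  tip_half_angle_deg: float) -> np.ndarray:
    """Conical-indenter contact force F = (2/pi) E/(1-nu^2) tan(alpha) d^2.

    delta in meters, returns Newtons.  Shared by the generator and the fitter
    as the single definition of the model.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    coef = (2.0 / np.pi) * modulus_pa / (1.0 - poisson_ratio ** 2) \
        * np.tan(np.deg2rad(tip_half_angle_deg))
    return coef * np.clip(delta_m, 0.0, None) ** 2


def simulate_force_curve(params: AfmSimParams, position_id: str = "p0",
                         cell_id: str = "cell0"):
    """Simulate one AFM approach curve (piezo z vs cantilever deflection).

    Before the contact point the deflection is zero-mean noise; beyond it the
    cantilever deflection d solves the force balance k*d = F_sneddon(z-z0-d),
    so indentation delta = (z - z0) - d and force k*d follow the conical
    Sneddon law exactly.  Piezo samples every ``sample_spacing`` nm until the
    indentation reaches ``max_indentation``.
    """
    from centrotrack.afm import ForceCurve

    params.validate()
    rng = np.random.default_rng(params.seed)
    k = params.spring_constant                      # N/m
    z0_m = params.contact_point * 1e-6
    dmax_m = params.max_indentation * 1e-9
    # piezo travel needed: z - z0 = delta + d(delta)
    d_at_max = sneddon_force(dmax_m, params.true_modulus,
                             params.poisson_ratio, params.tip_half_angle) / k
    z_max_m = z0_m + dmax_m + d_at_max
    step_m = params.sample_spacing * 1e-9
    z_m = np.arange(0.0, z_max_m + step_m, step_m)
    s = np.clip(z_m - z0_m, 0.0, None)              # piezo travel past contact
    coef = (2.0 / np.pi) * params.true_modulus / (1.0 - params.poisson_ratio ** 2) \
        * np.tan(np.deg2rad(params.tip_half_angle))
    # k*d = coef*(s-d)^2  ->  delta = (-k + sqrt(k^2 + 4*coef*k*s)) / (2*coef)
    delta = (-k + np.sqrt(k * k + 4.0 * coef * k * s)) / (2.0 * coef)
    defl_m = s - delta
    if params.noise_sd > 0:
        defl_m = defl_m + rng.normal(0.0, params.noise_sd * 1e-12 / k,
                                     size=defl_m.shape)
    return ForceCurve(
        piezo_z=z_m * 1e6,
        deflection=defl_m * 1e9,
        deflection_unit="nm",
        spring_constant=k,
        sensitivity=None,
        position_id=position_id,
        cell_id=cell_id,
    )
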