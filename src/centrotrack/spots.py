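"""3D localization of centrin1-GFP-like spots in calibrated 4D stacks.

The workflow mirrors anchor-based centrosome tracking: at anchor frames spots
are seeded (from provided click coordinates, or automatically from projection
maxima), the z coordinate is assigned as the slice maximizing the mean
intensity of the 500 x 500 nm region around the seed, detections at other
frames are found inside a spherical mask around a predicted position, and
every detection is refined to subpixel precision by fitting an anisotropic 3D
Gaussian.

Coordinate convention: physical µm, origin at the corner of voxel (0,0,0),
voxel centers at (i + 0.5) * spacing, all indices 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "ImageStack",
    "SpotObservation",
    "project_frame",
    "seed_anchor",
    "select_z",
    "detect_in_mask",
    "fit_gaussian_3d",
]


@dataclass
class ImageStack:
    """Calibrated 4D intensity data in (t, z, y, x) order."""

    data: np.ndarray
    pixel_size_xy: float
    z_spacing: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (t, z, y, x)")
        if min(self.pixel_size_xy, self.z_spacing, self.frame_interval) <= 0:
            raise ValueError("calibrations must be > 0")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def extent_um(self) -> np.ndarray:
        """Physical (x, y, z) extent of the volume in µm."""
        nt, nz, ny, nx = self.data.shape
        return np.array([nx * self.pixel_size_xy, ny * self.pixel_size_xy,
                         nz * self.z_spacing])

    def um_to_index(self, xyz_um) -> np.ndarray:
        """Continuous (z, y, x) voxel index of a physical (x, y, z) position."""
        x, y, z = np.asarray(xyz_um, dtype=float)
        return np.array([z / self.z_spacing - 0.5,
                         y / self.pixel_size_xy - 0.5,
                         x / self.pixel_size_xy - 0.5])

    def index_to_um(self, zyx_idx) -> np.ndarray:
        """Physical (x, y, z) µm position of a continuous (z, y, x) index."""
        zi, yi, xi = np.asarray(zyx_idx, dtype=float)
        return np.array([(xi + 0.5) * self.pixel_size_xy,
                         (yi + 0.5) * self.pixel_size_xy,
                         (zi + 0.5) * self.z_spacing])


@dataclass
class SpotObservation:
    """One localized spot: subpixel center in µm plus fit diagnostics."""

    frame: int
    center: np.ndarray            # (x, y, z) µm
    amplitude: float
    sigma: np.ndarray             # (sx, sy, sz) µm
    fit_residual: float
    source: str                   # "anchor-seed" | "propagated" | "centroid-fallback"


def project_frame(stack: ImageStack, frame: int) -> np.ndarray:
    """Maximum-intensity z-projection of one frame (y, x)."""
    return stack.data[frame].max(axis=0)


def _odd_window_px(size_um: float, pixel_um: float) -> int:
    """Odd pixel count nearest to a physical window size, minimum 1."""
    w = size_um / pixel_um
    lo = max(1, 2 * int((w - 1) // 2) + 1)
    hi = lo + 2
    return lo if (w - lo) <= (hi - w) else hi


def select_z(stack: ImageStack, frame: int, xy_um, window_um: float = 0.5) -> int:
    """z-slice with the maximum mean intensity of the 500 x 500 nm xy-region
    around the given position; ties broken toward the lower z index."""
    x, y = float(xy_um[0]), float(xy_um[1])
    nz, ny, nx = stack.data.shape[1:]
    xi = int(np.clip(np.floor(x / stack.pixel_size_xy), 0, nx - 1))
    yi = int(np.clip(np.floor(y / stack.pixel_size_xy), 0, ny - 1))
    half = _odd_window_px(window_um, stack.pixel_size_xy) // 2
    y0, y1 = max(0, yi - half), min(ny, yi + half + 1)
    x0, x1 = max(0, xi - half), min(nx, xi + half + 1)
    means = stack.data[frame, :, y0:y1, x0:x1].mean(axis=(1, 2))
    return int(np.argmax(means))      # argmax returns the lowest tied index


def seed_anchor(stack: ImageStack, frame: int, mode: str = "auto",
                seeds=None, threshold_k: float = 5.0,
                min_distance_um: float = 1.0) -> list[np.ndarray]:
    """Approximate 3D spot centers at an anchor frame.

    mode="provided" replays click coordinates (list of (x, y) µm); mode="auto"
    finds local maxima of the max projection above a robust threshold
    (median + k*MAD) with a minimum mutual distance.  Either way, z is
    assigned by :func:`select_z`.
    """
    if mode == "provided":
        if seeds is None:
            raise ValueError("mode='provided' requires seeds")
        xy_list = [np.asarray(s, dtype=float) for s in seeds]
    elif mode == "auto":
        from skimage.feature import peak_local_max

        proj = project_frame(stack, frame)
        med = np.median(proj)
        mad = np.median(np.abs(proj - med))
        thr = med + threshold_k * max(mad, 1e-12)
        min_px = max(1, int(round(min_distance_um / stack.pixel_size_xy)))
        peaks = peak_local_max(proj, min_distance=min_px,
                               threshold_abs=thr, exclude_border=False)
        if peaks.size == 0:
            warnings.warn(f"no spot maxima found at frame {frame}",
                          stacklevel=2)
            return []
        xy_list = [np.array([(c + 0.5) * stack.pixel_size_xy,
                             (r + 0.5) * stack.pixel_size_xy])
                   for r, c in peaks]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    centers = []
    for xy in xy_list:
        zi = select_z(stack, frame, xy)
        centers.append(np.array([xy[0], xy[1], (zi + 0.5) * stack.z_spacing]))
    return centers


def detect_in_mask(stack: ImageStack, frame: int, predicted_center,
                   radius_um: float,
                   threshold: float | None = None) -> np.ndarray | None:
    """Brightest voxel within a physical sphere about a predicted position.

    Distances are computed in µm so the anisotropy of the voxel grid is
    honored.  Returns the voxel-center position (x, y, z) in µm, or None when
    no voxel in the sphere exceeds the background threshold (default:
    median + 3*MAD of the frame).  Ties go to the voxel nearest the
    prediction, then lowest (z, y, x).
    """
    if radius_um <= 0:
        raise ValueError("radius must be > 0")
    vol = stack.data[frame]
    nz, ny, nx = vol.shape
    cx, cy, cz = np.asarray(predicted_center, dtype=float)
    z0 = max(0, int(np.floor((cz - radius_um) / stack.z_spacing - 0.5)))
    z1 = min(nz, int(np.ceil((cz + radius_um) / stack.z_spacing + 0.5)) + 1)
    y0 = max(0, int(np.floor((cy - radius_um) / stack.pixel_size_xy - 0.5)))
    y1 = min(ny, int(np.ceil((cy + radius_um) / stack.pixel_size_xy + 0.5)) + 1)
    x0 = max(0, int(np.floor((cx - radius_um) / stack.pixel_size_xy - 0.5)))
    x1 = min(nx, int(np.ceil((cx + radius_um) / stack.pixel_size_xy + 0.5)) + 1)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        warnings.warn("search sphere entirely outside volume", stacklevel=2)
        return None
    zc = (np.arange(z0, z1) + 0.5) * stack.z_spacing
    yc = (np.arange(y0, y1) + 0.5) * stack.pixel_size_xy
    xc = (np.arange(x0, x1) + 0.5) * stack.pixel_size_xy
    dist2 = ((zc[:, None, None] - cz) ** 2 + (yc[None, :, None] - cy) ** 2
             + (xc[None, None, :] - cx) ** 2)
    inside = dist2 <= radius_um ** 2
    if not inside.any():
        warnings.warn("search sphere entirely outside volume", stacklevel=2)
        return None
    sub = vol[z0:z1, y0:y1, x0:x1]
    if threshold is None:
        # robust noise floor plus a small dynamic-range margin so faint PSF
        # shoulders inside the sphere do not count as detections
        med = np.median(vol)
        mad = np.median(np.abs(vol - med))
        threshold = med + 3.0 * 1.4826 * mad + 0.02 * (vol.max() - med)
    vals = np.where(inside, sub, -np.inf)
    vmax = vals.max()
    if vmax <= threshold:
        return None
    cand = np.argwhere(vals == vmax)
    if len(cand) > 1:
        d2 = dist2[tuple(cand.T)]
        cand = cand[np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0], d2))]
    zi, yi, xi = cand[0]
    return np.array([xc[xi], yc[yi], zc[zi]])


def _gauss3d_model(params, zg, yg, xg):
    amp, x0, y0, z0, sx, sy, sz, off = params
    return off + amp * np.exp(
        -((xg - x0) ** 2) / (2 * sx ** 2)
        - ((yg - y0) ** 2) / (2 * sy ** 2)
        - ((zg - z0) ** 2) / (2 * sz ** 2))


def fit_gaussian_3d(stack: ImageStack, frame: int, approx_center,
                    window_xy: int = 7, window_z: int = 5,
                    source: str = "propagated") -> SpotObservation:
    """Subpixel refinement: axis-aligned anisotropic 3D Gaussian + offset,
    least-squares over a local window around the approximate center.

    A degenerate (flat) window or a failed fit falls back to the
    intensity-weighted centroid with ``source`` flagged accordingly.
    """
    vol = stack.data[frame]
    nz, ny, nx = vol.shape
    zi, yi, xi = np.round(stack.um_to_index(approx_center)).astype(int)
    hz, hxy = window_z // 2, window_xy // 2
    z0, z1 = max(0, zi - hz), min(nz, zi + hz + 1)
    y0, y1 = max(0, yi - hxy), min(ny, yi + hxy + 1)
    x0, x1 = max(0, xi - hxy), min(nx, xi + hxy + 1)
    sub = vol[z0:z1, y0:y1, x0:x1].astype(float)
    zc = (np.arange(z0, z1) + 0.5) * stack.z_spacing
    yc = (np.arange(y0, y1) + 0.5) * stack.pixel_size_xy
    xc = (np.arange(x0, x1) + 0.5) * stack.pixel_size_xy
    zg, yg, xg = np.meshgrid(zc, yc, xc, indexing="ij")
    off0 = float(sub.min())
    amp0 = float(sub.max() - off0)
    span = sub - off0

    def _centroid_obs() -> SpotObservation:
        w = np.clip(span, 0.0, None)
        tot = w.sum()
        if tot <= 0:
            center = np.asarray(approx_center, dtype=float)
        else:
            center = np.array([(w * xg).sum(), (w * yg).sum(),
                               (w * zg).sum()]) / tot
        return SpotObservation(
            frame=frame, center=center, amplitude=max(amp0, 1e-12),
            sigma=np.array([stack.pixel_size_xy, stack.pixel_size_xy,
                            stack.z_spacing]),
            fit_residual=np.nan, source="centroid-fallback")

    if amp0 <= 0 or sub.size < 10:
        return _centroid_obs()
    w = span
    tot = w.sum()
    cx0 = float((w * xg).sum() / tot)
    cy0 = float((w * yg).sum() / tot)
    cz0 = float((w * zg).sum() / tot)
    p0 = [amp0, cx0, cy0, cz0,
          stack.pixel_size_xy, stack.pixel_size_xy, stack.z_spacing, off0]
    lb = [1e-12, xc[0] - stack.pixel_size_xy, yc[0] - stack.pixel_size_xy,
          zc[0] - stack.z_spacing, stack.pixel_size_xy / 10,
          stack.pixel_size_xy / 10, stack.z_spacing / 10, 0.0]
    ub = [np.inf, xc[-1] + stack.pixel_size_xy, yc[-1] + stack.pixel_size_xy,
          zc[-1] + stack.z_spacing, 10.0, 10.0, 10.0,
          float(sub.max()) + 1e-9]
    p0 = np.clip(p0, lb, ub)
    try:
        res = optimize.least_squares(
            lambda p: (_gauss3d_model(p, zg, yg, xg) - sub).ravel(),
            p0, bounds=(lb, ub), method="trf", xtol=1e-12, ftol=1e-12)
        if not res.success:
            raise RuntimeError(res.message)
    except Exception:
        return _centroid_obs()
    amp, fx, fy, fz, sx, sy, sz, _ = res.x
    resid = float(np.sqrt(np.mean(res.fun ** 2)))
    return SpotObservation(
        frame=frame, center=np.array([fx, fy, fz]), amplitude=float(amp),
        sigma=np.array([sx, sy, sz]), fit_residual=resid, source=source)
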