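"""AFM force-curve post-processing into apparent elastic moduli.

An approach curve records cantilever deflection d against piezo displacement
z.  On glass the cantilever deflects one-for-one past contact, which
calibrates the deflection sensitivity.  On a cell, the contact point z0 is
found by joint residual minimization (flat baseline before z0, conical
Sneddon response after), the indentation is delta = (z - z0) - d, curves are
averaged per probed position, and the apparent elastic modulus E comes from a
least-squares fit of

    F = (2/pi) * E / (1 - nu^2) * tan(alpha) * delta^2

restricted to indentations shallower than 800 nm so the cortex, not the
cytoplasm, dominates the restoring force.  Per-cell values aggregate the four
probed positions (the vertices of a 2-µm square over the cell center).

Units: piezo_z in µm, deflection in nm (or V plus a sensitivity in nm/V),
spring constant in N/m, forces in pN, indentation in nm, moduli in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ForceCurve",
    "ElasticityEstimate",
    "sensitivity_from_glass",
    "find_contact_point",
    "indentation_force",
    "average_position_curves",
    "fit_sneddon",
    "cell_elasticity",
    "MAX_DEPTH_NM",
]

MAX_DEPTH_NM = 800.0
DEFAULT_TIP_HALF_ANGLE = 35.0
DEFAULT_POISSON_RATIO = 0.5


@dataclass
class ForceCurve:
    """One AFM approach segment."""

    piezo_z: np.ndarray            # µm, strictly increasing toward the sample
    deflection: np.ndarray         # nm, or V when deflection_unit == "V"
    spring_constant: float         # N/m
    deflection_unit: str = "nm"
    sensitivity: float | None = None   # nm/V, required when unit is V
    position_id: str = "p0"
    cell_id: str = "cell0"

    def __post_init__(self) -> None:
        self.piezo_z = np.asarray(self.piezo_z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.piezo_z.shape != self.deflection.shape:
            raise ValueError("piezo_z and deflection must have equal length")
        if np.any(np.diff(self.piezo_z) <= 0):
            raise ValueError("piezo_z must be strictly monotone on the approach")
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if self.deflection_unit not in ("nm", "V"):
            raise ValueError("deflection_unit must be 'nm' or 'V'")

    def deflection_nm(self) -> np.ndarray:
        if self.deflection_unit == "nm":
            return self.deflection
        if self.sensitivity is None:
            raise ValueError("deflection in V requires a sensitivity (nm/V)")
        return self.deflection * self.sensitivity

    @property
    def sample_spacing_um(self) -> float:
        return float(np.median(np.diff(self.piezo_z)))


@dataclass
class ElasticityEstimate:
    position_id: str
    contact_point_um: float
    apparent_modulus_pa: float
    fit_rms_pn: float
    depth_used_nm: float
    n_curves_averaged: int = 1


def _sneddon_coef(modulus_pa: float, poisson_ratio: float,
                  tip_half_angle_deg: float) -> float:
    return (2.0 / np.pi) * modulus_pa / (1.0 - poisson_ratio ** 2) \
        * np.tan(np.deg2rad(tip_half_angle_deg))


def sensitivity_from_glass(curve: ForceCurve) -> float:
    """Deflection sensitivity from a curve acquired on rigid glass.

    On glass the tip does not indent, so past contact the deflection rises
    linearly with piezo travel with unit physical slope; the robust
    (Theil-Sen) slope of the upper half of the deflection range therefore
    converts the recorded signal to physical length.  For a curve recorded in
    V the result is nm deflection per V; for a curve already in nm it is the
    dimensionless slope (1.0 for an ideal cantilever in matched units).
    """
    z_nm = curve.piezo_z * 1000.0
    d = curve.deflection
    span = d.max() - d.min()
    if span <= 0:
        raise ValueError("no contact region found on glass curve")
    post = d > d.min() + 0.5 * span
    if post.sum() < 5:
        raise ValueError("no linear post-contact region found on glass curve")
    slope = stats.theilslopes(d[post], z_nm[post]).slope
    if slope <= 0:
        raise ValueError("non-positive contact slope on glass curve")
    if curve.deflection_unit == "V":
        return 1.0 / slope          # (V per nm)^-1 = nm per V
    return float(slope)


def _force_pn(curve: ForceCurve) -> np.ndarray:
    # k [N/m] * d [nm] = k*d nN*... 0.006 N/m * 1 nm = 6 pN -> k*d*1000 in pN
    return curve.spring_constant * curve.deflection_nm() * 1000.0


def find_contact_point(curve: ForceCurve) -> float:
    """Contact point z0 (µm) by joint piecewise-model residual scan.

    Every sampled z is tried as a candidate z0: the samples before it are fit
    by a constant baseline, the samples beyond by the Sneddon quadratic in
    the implied indentation, and the candidate minimizing the combined sum of
    squared force residuals wins; parabolic interpolation of the residual
    profile around the winner refines z0 off the grid.
    """
    z = curve.piezo_z
    f = _force_pn(curve)
    d_nm = curve.deflection_nm()
    n = z.size
    if n < 10:
        raise ValueError("too few samples to locate a contact point")
    sse = np.full(n, np.inf)
    lo, hi = 2, n - 5
    for i in range(lo, hi):
        base = f[:i].mean()
        r0 = f[:i] - base
        delta_nm = (z[i:] - z[i]) * 1000.0 - (d_nm[i:] - d_nm[:i].mean())
        g = np.clip(delta_nm, 0.0, None) ** 2
        denom = float(g @ g)
        fc = f[i:] - base
        coef = float(g @ fc) / denom if denom > 0 else 0.0
        r1 = fc - coef * g
        sse[i] = float(r0 @ r0 + r1 @ r1)
    i0 = int(np.argmin(sse))
    if not np.isfinite(sse[i0]):
        raise ValueError("no contact point found")
    # the piecewise model must beat a flat baseline clearly, otherwise the
    # curve contains no contact (residual profile is essentially flat)
    sse_flat = float(np.sum((f - f.mean()) ** 2))
    if sse[i0] >= 0.95 * sse_flat:
        raise ValueError("residual profile is flat: no contact detected")
    if lo < i0 < hi - 1:
        y0, y1, y2 = sse[i0 - 1], sse[i0], sse[i0 + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if denom > 0 else 0.0
        shift = float(np.clip(shift, -0.5, 0.5))
    else:
        shift = 0.0
    step = curve.sample_spacing_um
    return float(z[i0] + shift * step)


def indentation_force(curve: ForceCurve, z0_um: float):
    """Indentation depth and force beyond the contact point.

    delta = (z - z0) - d with the deflection d converted to length, and
    F = k * d.  Returns (delta_nm, force_pn); samples with negative
    indentation are dropped.  The pre-contact deflection baseline (mean
    before z0) is subtracted first.
    """
    if not (curve.piezo_z[0] <= z0_um <= curve.piezo_z[-1]):
        raise ValueError("contact point outside curve range")
    d_nm = curve.deflection_nm()
    pre = curve.piezo_z < z0_um
    baseline = d_nm[pre].mean() if pre.any() else 0.0
    post = curve.piezo_z >= z0_um
    d_post = d_nm[post] - baseline
    delta = (curve.piezo_z[post] - z0_um) * 1000.0 - d_post
    force = curve.spring_constant * d_post * 1000.0
    keep = delta >= 0
    return delta[keep], force[keep]


def average_position_curves(delta_force_pairs: list):
    """Pointwise average of force-indentation curves from one position.

    Curves are resampled onto a common indentation grid spanning the overlap
    of their ranges.  Returns (delta_nm, mean_force_pn, n_curves).
    """
    if not delta_force_pairs:
        raise ValueError("need at least one curve")
    los = [float(d.min()) for d, _ in delta_force_pairs]
    his = [float(d.max()) for d, _ in delta_force_pairs]
    lo, hi = max(los), min(his)
    if hi <= lo:
        raise ValueError("curves have disjoint indentation ranges")
    n_pts = max(int(min(len(d) for d, _ in delta_force_pairs)), 10)
    grid = np.linspace(lo, hi, n_pts)
    stackd = []
    for d, f in delta_force_pairs:
        order = np.argsort(d)
        stackd.append(np.interp(grid, d[order], f[order]))
    return grid, np.mean(stackd, axis=0), len(delta_force_pairs)


def fit_sneddon(delta_nm: np.ndarray, force_pn: np.ndarray,
                max_depth_nm: float = MAX_DEPTH_NM,
                tip_half_angle_deg: float = DEFAULT_TIP_HALF_ANGLE,
                poisson_ratio: float = DEFAULT_POISSON_RATIO,
                position_id: str = "p0", contact_point_um: float = np.nan,
                n_curves_averaged: int = 1) -> ElasticityEstimate:
    """Least-squares conical Sneddon fit restricted to shallow indentations.

    Fits F = (2/pi) E/(1-nu^2) tan(alpha) delta^2 over 0 < delta <=
    ``max_depth_nm``; the model is linear in E so the fit is closed-form.
    """
    delta_nm = np.asarray(delta_nm, dtype=float)
    force_pn = np.asarray(force_pn, dtype=float)
    sel = (delta_nm > 0) & (delta_nm <= max_depth_nm)
    if sel.sum() < 10:
        raise ValueError(
            f"need >= 10 samples with 0 < delta <= {max_depth_nm} nm")
    dm = delta_nm[sel] * 1e-9
    fn = force_pn[sel] * 1e-12
    g = _sneddon_coef(1.0, poisson_ratio, tip_half_angle_deg) * dm ** 2
    modulus = float(g @ fn) / float(g @ g)
    if modulus <= 0:
        raise ValueError("fitted modulus is non-positive")
    resid = fn - modulus * g
    return ElasticityEstimate(
        position_id=position_id,
        contact_point_um=contact_point_um,
        apparent_modulus_pa=modulus,
        fit_rms_pn=float(np.sqrt(np.mean(resid ** 2)) * 1e12),
        depth_used_nm=float(delta_nm[sel].max()),
        n_curves_averaged=n_curves_averaged)


def cell_elasticity(estimates: list[ElasticityEstimate]) -> dict:
    """Per-cell summary of position moduli (mean, SD, n, positions)."""
    if not estimates:
        raise ValueError("need at least one position estimate")
    moduli = np.array([e.apparent_modulus_pa for e in estimates])
    return {
        "mean_modulus_pa": float(moduli.mean()),
        "sd_modulus_pa": float(moduli.std(ddof=1)) if moduli.size > 1 else 0.0,
        "n_positions": int(moduli.size),
        "positions": [e.position_id for e in estimates],
        "moduli_pa": moduli.tolist(),
    }
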