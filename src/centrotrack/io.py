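"""File formats: OME-TIFF stacks, CSV tables, TSV force curves, JSON sidecars.

Units in files are always µm, s and Pa; nothing is autodetected.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from centrotrack.afm import ForceCurve
from centrotrack.linker import Trajectory
from centrotrack.spots import ImageStack, SpotObservation


def write_stack(path, stack: ImageStack) -> None:
    """OME-TIFF in TZYX order with physical sizes in the metadata."""
    tifffile.imwrite(
        path, stack.data.astype(np.float32),
        metadata={
            "axes": "TZYX",
            "PhysicalSizeX": stack.pixel_size_xy, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_xy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": stack.z_spacing, "PhysicalSizeZUnit": "µm",
            "TimeIncrement": stack.frame_interval, "TimeIncrementUnit": "s",
        },
        ome=True)


def read_stack(path, pixel_size_xy: float | None = None,
               z_spacing: float | None = None,
               frame_interval: float | None = None) -> ImageStack:
    """Read an OME-TIFF stack; calibration comes from metadata unless given."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = {}
        if tf.ome_metadata:
            try:
                import xml.etree.ElementTree as ET
                root = ET.fromstring(tf.ome_metadata)
                ns = {"ome": root.tag.split("}")[0].strip("{")}
                px = root.find(".//ome:Pixels", ns)
                meta = px.attrib if px is not None else {}
            except Exception:
                meta = {}
    if data.ndim == 3:
        data = data[None]
    pixel_size_xy = pixel_size_xy or float(meta.get("PhysicalSizeX", 0) or 0)
    z_spacing = z_spacing or float(meta.get("PhysicalSizeZ", 0) or 0)
    frame_interval = frame_interval or float(meta.get("TimeIncrement", 0) or 0)
    if min(pixel_size_xy, z_spacing, frame_interval) <= 0:
        raise ValueError(
            "stack calibration missing from metadata; pass pixel_size_xy, "
            "z_spacing and frame_interval explicitly")
    return ImageStack(data=np.asarray(data, dtype=float),
                      pixel_size_xy=pixel_size_xy, z_spacing=z_spacing,
                      frame_interval=frame_interval)


def write_truth_csv(path, truth) -> None:
    rows = []
    for t in range(truth.n_frames):
        for c in range(truth.positions.shape[1]):
            x, y, z = truth.positions[t, c]
            rows.append((t, c, x, y, z))
    pd.DataFrame(rows, columns=["frame", "centrosome_id", "x_um", "y_um",
                                "z_um"]).to_csv(path, index=False)


def write_truth_sidecar(path, truth) -> None:
    from dataclasses import asdict

    payload = {
        "completion_frame": truth.completion_frame,
        "motorized_onset_frame": truth.motorized_onset_frame,
        "anaphase_onset_frame": truth.anaphase_onset_frame,
        "frame_interval_s": truth.frame_interval,
        "params": asdict(truth.params) if truth.params is not None else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_seeds_csv(path) -> dict[int, list]:
    """Click/seed files: columns frame, x_um, y_um."""
    df = pd.read_csv(path)
    out: dict[int, list] = {}
    for _, row in df.iterrows():
        out.setdefault(int(row["frame"]), []).append(
            np.array([row["x_um"], row["y_um"]]))
    return out


def write_spots_csv(path, spots_by_frame: dict[int, list[SpotObservation]]) -> None:
    rows = []
    for frame in sorted(spots_by_frame):
        for i, o in enumerate(spots_by_frame[frame]):
            rows.append((o.frame, i, *o.center, o.amplitude, o.fit_residual,
                         o.source))
    pd.DataFrame(rows, columns=["frame", "spot_id", "x_um", "y_um", "z_um",
                                "amplitude", "residual", "source"]
                 ).to_csv(path, index=False)


def write_trajectories_csv(path, tracks: list[Trajectory],
                           frame_interval_s: float) -> None:
    rows = []
    for tr in tracks:
        for o in tr.observations:
            rows.append((tr.centrosome_id, o.frame, o.frame * frame_interval_s,
                         *o.center, o.source == "interpolated"))
    pd.DataFrame(rows, columns=["centrosome_id", "frame", "time_s", "x_um",
                                "y_um", "z_um", "interpolated_flag"]
                 ).to_csv(path, index=False)


def read_trajectories_csv(path) -> list[Trajectory]:
    df = pd.read_csv(path)
    tracks = []
    for tid, grp in df.groupby("centrosome_id"):
        obs = [SpotObservation(
            frame=int(r.frame),
            center=np.array([r.x_um, r.y_um, r.z_um]),
            amplitude=1.0, sigma=np.ones(3), fit_residual=np.nan,
            source="interpolated" if bool(r.interpolated_flag) else "propagated")
            for r in grp.sort_values("frame").itertuples()]
        tracks.append(Trajectory(centrosome_id=int(tid), observations=obs))
    return tracks


def read_poles_csv(path) -> list:
    """Pole tables: cell_id, pole_index, x_um, y_um[, z_um], condition."""
    from centrotrack.geometry import TripolarSpindle

    df = pd.read_csv(path)
    has_z = "z_um" in df.columns
    spindles = []
    for cell, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("pole_index")
        cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
        cond = str(grp["condition"].iloc[0]) if "condition" in grp else ""
        spindles.append(TripolarSpindle(cell_id=str(cell),
                                        poles=grp[cols].to_numpy(),
                                        condition_label=cond))
    return spindles


def write_force_curve_tsv(path, curve: ForceCurve, meta_path=None) -> None:
    pd.DataFrame({"z_um": curve.piezo_z,
                  f"deflection_{curve.deflection_unit}": curve.deflection}
                 ).to_csv(path, sep="\t", index=False)
    if meta_path is not None:
        Path(meta_path).write_text(json.dumps({
            "spring_constant_n_per_m": curve.spring_constant,
            "sensitivity_nm_per_v": curve.sensitivity,
            "deflection_unit": curve.deflection_unit,
            "position_id": curve.position_id,
            "cell_id": curve.cell_id,
        }, indent=2))


def read_force_curve_tsv(path, meta_path=None, spring_constant=None) -> ForceCurve:
    df = pd.read_csv(path, sep="\t")
    meta = {}
    if meta_path is not None:
        meta = json.loads(Path(meta_path).read_text())
    unit = meta.get("deflection_unit", "nm")
    col = f"deflection_{unit}"
    if col not in df.columns:
        col = [c for c in df.columns if c.startswith("deflection")][0]
        unit = col.split("_", 1)[1] if "_" in col else "nm"
    k = spring_constant or meta.get("spring_constant_n_per_m")
    if k is None:
        raise ValueError("spring constant missing: give it or a metadata file")
    return ForceCurve(piezo_z=df["z_um"].to_numpy(),
                      deflection=df[col].to_numpy(),
                      deflection_unit=unit,
                      spring_constant=float(k),
                      sensitivity=meta.get("sensitivity_nm_per_v"),
                      position_id=meta.get("position_id", "p0"),
                      cell_id=meta.get("cell_id", "cell0"))
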