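"""File formats: apparatus JSON configs, measurement CSVs, landmark CSVs.

Dialects
--------
* Apparatus config: JSON, schema id ``bitemech/apparatus-v1``.  Keys:
  ``joint_centre``, ``rotation_axis``, ``inlever``, ``outlever_distal``,
  ``outlever_proximal``, ``apodeme_axis`` (3-element arrays, mm),
  ``gamma0_deg``, ``theta0_deg``, ``theta_range_deg``; ``muscle`` block
  with ``volume_mm3``, ``populations`` (``phi0_deg``,
  ``fibre_length0_mm``, ``filament_length_mm``, ``number_fraction``) and
  ``physiology`` (``sigma_max_MPa``, ``L_opt_mm``, ``beta``); optional
  ``units`` block which must declare degrees/mm.
* Measurements: CSV, comma-separated, UTF-8, '.' decimal, header
  mandatory.  Columns ``theta_deg``, ``force_N``; optional sensor
  columns ``outlever_x/y/z``, ``sensor_x/y/z``, ``plate_moment_cal_mm``,
  ``plate_moment_bite_mm``, ``contact``.
* Landmarks: CSV with columns ``id``, ``pose``, ``hemisphere``,
  ``landmark``, ``x``, ``y``, ``z`` (mm).

All invariants of the domain types are checked at load time; violations
are reported with row/key context.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .biteforce import BiteApparatus, BiteMeasurement
from .geometry import JointFrame, LeverSet
from .muscle import FibrePopulation, ForceLengthParams, MuscleArchitecture

__all__ = [
    "SCHEMA_ID",
    "read_apparatus",
    "write_apparatus",
    "read_measurements",
    "write_measurements",
    "read_landmarks",
]

SCHEMA_ID = "bitemech/apparatus-v1"

_MEAS_COLUMNS = ("theta_deg", "force_N")


def _check_units(cfg: dict, path) -> None:
    units = cfg.get("units", {})
    angle = units.get("angle", "deg")
    length = units.get("length", "mm")
    if angle not in ("deg", "degree", "degrees"):
        raise ValueError(
            f"{path}: config declares angle unit {angle!r}; this reader "
            "expects degrees — convert the file, do not reinterpret it"
        )
    if length not in ("mm", "millimetre", "millimeter"):
        raise ValueError(
            f"{path}: config declares length unit {length!r}; this reader "
            "expects millimetres — convert the file, do not reinterpret it"
        )


def read_apparatus(path) -> BiteApparatus:
    """Load and fully validate an apparatus JSON config."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        cfg = json.load(fh)
    _check_units(cfg, path)
    try:
        frame = JointFrame(centre=cfg["joint_centre"], axis=cfg["rotation_axis"])
        levers = LeverSet(
            inlever=cfg["inlever"],
            outlever_distal=cfg["outlever_distal"],
            outlever_proximal=cfg["outlever_proximal"],
            apodeme_axis=cfg["apodeme_axis"],
            gamma0=float(cfg["gamma0_deg"]),
            theta0=float(cfg["theta0_deg"]),
        )
        mus = cfg["muscle"]
        muscle = MuscleArchitecture(
            volume=float(mus["volume_mm3"]),
            populations=[
                FibrePopulation(
                    phi0=float(p["phi0_deg"]),
                    fibre_length0=float(p["fibre_length0_mm"]),
                    filament_length=float(p.get("filament_length_mm", 0.0)),
                    number_fraction=float(p["number_fraction"]),
                )
                for p in mus["populations"]
            ],
        )
        phys = mus["physiology"]
        physiology = ForceLengthParams(
            sigma_max=float(phys["sigma_max_MPa"]),
            l_opt=float(phys["L_opt_mm"]),
            beta=float(phys["beta"]),
        )
    except KeyError as exc:
        raise ValueError(f"{path}: missing config key {exc}") from exc
    theta_range = tuple(cfg.get("theta_range_deg", (35.0, 105.0)))
    return BiteApparatus(
        frame=frame,
        levers=levers,
        muscle=muscle,
        physiology=physiology,
        theta_range=theta_range,
        pooled_a_phys=bool(cfg.get("pooled_a_phys", True)),
    )


def write_apparatus(apparatus: BiteApparatus, path) -> None:
    """Write an apparatus to the JSON dialect (round-trips with the reader)."""
    cfg = {
        "schema": SCHEMA_ID,
        "units": {"angle": "deg", "length": "mm"},
        "joint_centre": apparatus.frame.centre.tolist(),
        "rotation_axis": apparatus.frame.axis.tolist(),
        "inlever": apparatus.levers.inlever.tolist(),
        "outlever_distal": apparatus.levers.outlever_distal.tolist(),
        "outlever_proximal": apparatus.levers.outlever_proximal.tolist(),
        "apodeme_axis": apparatus.levers.apodeme_axis.tolist(),
        "gamma0_deg": apparatus.levers.gamma0,
        "theta0_deg": apparatus.levers.theta0,
        "theta_range_deg": list(apparatus.theta_range),
        "pooled_a_phys": apparatus.pooled_a_phys,
        "muscle": {
            "volume_mm3": apparatus.muscle.volume,
            "populations": [
                {
                    "phi0_deg": p.phi0,
                    "fibre_length0_mm": p.fibre_length0,
                    "filament_length_mm": p.filament_length,
                    "number_fraction": p.number_fraction,
                }
                for p in apparatus.muscle.populations
            ],
            "physiology": {
                "sigma_max_MPa": apparatus.physiology.sigma_max,
                "L_opt_mm": apparatus.physiology.l_opt,
                "beta": apparatus.physiology.beta,
            },
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2)
        fh.write("\n")


def read_measurements(path) -> list[BiteMeasurement]:
    """Load a measurement CSV into validated :class:`BiteMeasurement` rows."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MEAS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        kwargs = {"theta": float(row["theta_deg"]), "force_measured": float(row["force_N"])}
        if {"outlever_x", "outlever_y", "outlever_z"} <= set(df.columns):
            kwargs["outlever"] = np.array(
                [row["outlever_x"], row["outlever_y"], row["outlever_z"]], float
            )
        if {"sensor_x", "sensor_y", "sensor_z"} <= set(df.columns):
            kwargs["sensor_axis"] = np.array(
                [row["sensor_x"], row["sensor_y"], row["sensor_z"]], float
            )
        if "plate_moment_cal_mm" in df.columns:
            kwargs["plate_moment_cal"] = float(row["plate_moment_cal_mm"])
        if "plate_moment_bite_mm" in df.columns:
            kwargs["plate_moment_bite"] = float(row["plate_moment_bite_mm"])
        if "contact" in df.columns:
            kwargs["contact"] = str(row["contact"])
        try:
            out.append(BiteMeasurement(**kwargs))
        except ValueError as exc:
            raise ValueError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_measurements(measurements: list[BiteMeasurement], path) -> None:
    """Write measurements to the CSV dialect (round-trips with the reader)."""
    rows = []
    for m in measurements:
        rows.append(
            {
                "theta_deg": m.theta,
                "force_N": m.force_measured,
                "outlever_x": m.outlever[0],
                "outlever_y": m.outlever[1],
                "outlever_z": m.outlever[2],
                "sensor_x": m.sensor_axis[0],
                "sensor_y": m.sensor_axis[1],
                "sensor_z": m.sensor_axis[2],
                "plate_moment_cal_mm": m.plate_moment_cal,
                "plate_moment_bite_mm": m.plate_moment_bite,
                "contact": m.contact,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks(path) -> pd.DataFrame:
    """Load a landmark CSV (long format) for :func:`normalize_landmarks`."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {"pose", "hemisphere", "landmark", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    bad = ~df["hemisphere"].isin(["left", "right"])
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 2
        raise ValueError(
            f"{path}: row {row}: hemisphere must be 'left' or 'right'"
        )
    return df
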