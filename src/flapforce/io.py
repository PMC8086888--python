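"""Dataset bundle reading/writing and harmonic JSON serialization.

A dataset bundle is a directory with a ``manifest.json`` describing insects,
sequences, morphology and air properties, one kinematics CSV per flight
sequence, and a sidecar units declaration.  Angles may be declared in
degrees, in which case they are converted to radians on read (and the
conversion is logged); all other quantities are SI (metres, seconds,
kilograms).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import HarmonicSeries, RawSequence
from .morphology import WingPlanform

__all__ = [
    "DatasetBundle",
    "read_dataset",
    "write_dataset",
    "harmonics_to_json",
    "harmonics_from_json",
    "planform_to_dict",
    "planform_from_dict",
]

log = logging.getLogger("flapforce.io")

CSV_COLUMNS = ["t", "X", "Y", "Z", "yaw", "pitch", "roll",
               "phi_L", "theta_L", "omega0_L", "omega_r_L",
               "phi_R", "theta_R", "omega0_R", "omega_r_R"]

MANIFEST_VERSION = 1


@dataclass
class DatasetBundle:
    """In-memory form of a dataset directory."""

    sequences: list[RawSequence]
    planforms: dict[str, WingPlanform]
    rho: float
    manifest: dict


def planform_to_dict(pf: WingPlanform) -> dict:
    return {"length": pf.length, "side": pf.side,
            "wing_base_offset": list(pf.wing_base_offset),
            "stations": [{"r": float(r), "chord": float(c),
                          "axis_offset_le": float(a)}
                         for r, c, a in zip(pf.r, pf.chord,
                                            pf.axis_offset_le)]}


def planform_from_dict(d: dict) -> WingPlanform:
    st = d["stations"]
    return WingPlanform(length=d["length"],
                        r=[s["r"] for s in st],
                        chord=[s["chord"] for s in st],
                        axis_offset_le=[s["axis_offset_le"] for s in st],
                        side=d.get("side", "right"),
                        wing_base_offset=np.asarray(
                            d.get("wing_base_offset", [0, 0, 0]), float))


def write_dataset(path, sequences: list[RawSequence],
                  planforms: dict[str, WingPlanform],
                  rho: float, provenance: dict | None = None) -> Path:
    """Write a dataset bundle directory (manifest + per-sequence CSVs)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    seq_entries = []
    for seq in sequences:
        fname = f"{seq.sequence_id}.csv"
        om = {side: seq.twist_series(side) for side in ("left", "right")}
        df = pd.DataFrame({
            "t": seq.t,
            "X": seq.body_position[:, 0], "Y": seq.body_position[:, 1],
            "Z": seq.body_position[:, 2],
            "yaw": seq.body_euler[:, 0], "pitch": seq.body_euler[:, 1],
            "roll": seq.body_euler[:, 2],
            "phi_L": seq.wings["left"]["phi"],
            "theta_L": seq.wings["left"]["theta"],
            "omega0_L": om["left"][0], "omega_r_L": om["left"][1],
            "phi_R": seq.wings["right"]["phi"],
            "theta_R": seq.wings["right"]["theta"],
            "omega0_R": om["right"][0], "omega_r_R": om["right"][1],
        })
        df.to_csv(path / fname, index=False, float_format="%.17g")
        seq_entries.append({"sequence_id": seq.sequence_id,
                            "insect_id": seq.insect_id,
                            "file": fname, "mass": seq.mass,
                            "n_samples": len(seq.t)})
    manifest = {
        "version": MANIFEST_VERSION,
        "units": {"length": "m", "time": "s", "angle": "rad", "mass": "kg"},
        "air": {"rho": rho},
        "morphology": {side: planform_to_dict(pf)
                       for side, pf in planforms.items()},
        "sequences": seq_entries,
        "provenance": provenance or {},
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path


def read_dataset(path) -> DatasetBundle:
    """Read and validate a dataset bundle directory."""
    path = Path(path)
    mf_path = path / "manifest.json"
    if not mf_path.exists():
        raise FileNotFoundError(f"no manifest.json under {path}")
    with open(mf_path) as fh:
        manifest = json.load(fh)
    for field in ("units", "air", "morphology", "sequences"):
        if field not in manifest:
            raise ValueError(f"manifest missing required field {field!r}")
    angle_unit = manifest["units"].get("angle", "rad")
    if angle_unit not in ("rad", "deg"):
        raise ValueError(f"unsupported angle unit {angle_unit!r}")
    scale = np.pi / 180.0 if angle_unit == "deg" else 1.0
    if angle_unit == "deg":
        log.info("angle unit declared in degrees; converting to radians")
    rho = float(manifest["air"]["rho"])
    planforms = {side: planform_from_dict(d)
                 for side, d in manifest["morphology"].items()}
    sequences = []
    for entry in manifest["sequences"]:
        sid = entry.get("sequence_id", "?")
        if entry.get("mass") is None:
            raise ValueError(f"sequence {sid!r}: missing mass")
        df = pd.read_csv(path / entry["file"])
        missing = set(CSV_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"sequence {sid!r}: missing columns {missing}")
        t = df["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"sequence {sid!r}: non-monotonic time stamps")
        wings = {}
        for side, suffix in (("left", "L"), ("right", "R")):
            wings[side] = {
                "phi": df[f"phi_{suffix}"].to_numpy() * scale,
                "theta": df[f"theta_{suffix}"].to_numpy() * scale,
                "omega0": df[f"omega0_{suffix}"].to_numpy() * scale,
                "omega_r": df[f"omega_r_{suffix}"].to_numpy() * scale,
            }
        sequences.append(RawSequence(
            t=t,
            body_position=df[["X", "Y", "Z"]].to_numpy(),
            body_euler=df[["yaw", "pitch", "roll"]].to_numpy() * scale,
            wings=wings,
            insect_id=entry.get("insect_id", "unknown"),
            sequence_id=sid, mass=float(entry["mass"]), rho=rho))
    return DatasetBundle(sequences=sequences, planforms=planforms,
                         rho=rho, manifest=manifest)


# ---------------------------------------------------------------------------
# Harmonic JSON
# ---------------------------------------------------------------------------

def harmonics_to_json(harmonics: dict, period: float, mass: float,
                      rho: float, path=None) -> dict:
    """Serialize per-channel harmonic series (bit-exact round trip)."""
    doc = {"period": period, "fundamental": 1.0 / period,
           "mass": mass, "rho": rho, "channels": {}}
    for side, chans in harmonics.items():
        doc["channels"][side] = {}
        for key, s in chans.items():
            doc["channels"][side][key] = {
                "order": s.order,
                "poly": list(s.poly),
                "cos": list(s.cos_coeffs),
                "sin": list(s.sin_coeffs),
                "captured_variance": s.captured_variance,
            }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    return doc


def harmonics_from_json(doc_or_path) -> tuple[dict, dict]:
    """Inverse of :func:`harmonics_to_json`; returns (harmonics, meta)."""
    if isinstance(doc_or_path, (str, Path)):
        with open(doc_or_path) as fh:
            doc = json.load(fh)
    else:
        doc = doc_or_path
    harmonics = {}
    for side, chans in doc["channels"].items():
        harmonics[side] = {}
        for key, d in chans.items():
            harmonics[side][key] = HarmonicSeries(
                period=doc["period"], order=d["order"],
                poly=np.asarray(d["poly"]),
                cos_coeffs=np.asarray(d["cos"]),
                sin_coeffs=np.asarray(d["sin"]),
                captured_variance=d.get("captured_variance", 1.0))
    meta = {k: doc[k] for k in ("period", "fundamental", "mass", "rho")}
    return harmonics, meta
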