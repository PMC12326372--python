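"""Readers and writers for spin systems, 1D spectra and 2D maps.

Spin systems are stored as JSON or YAML with keys::

    g: [gX, gY, gZ]
    nuclei:
      - isotope: "15N"
        position: "5"
        A: [Ax, Ay, Az]          # MHz
        A_frame: [alpha, beta, gamma]   # degrees, optional
        Q: [Q1, Q2, Q3]          # MHz, traceless, I=1 nuclei only
        Q_frame: [alpha, beta, gamma]   # optional

1D spectra are two-column delimited text with ``# key: value`` header
comments; 2D maps are either delimited text with two axis header rows or
HDF5 datasets with axis attributes.  All loaders re-validate the
structural invariants, so a file with a quadrupole block on an I=1/2
nucleus or a non-traceless Q is rejected.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .fieldsweep import Spectrum1D
from .hyperfine_spectroscopy import Map2D
from .spin_system import (
    GTensor,
    Nucleus,
    PrincipalTensor,
    SpinSystem,
    ValidationError,
)

__all__ = [
    "read_spin_system",
    "write_spin_system",
    "read_spectrum1d",
    "write_spectrum1d",
    "read_map2d",
    "write_map2d",
]


def _system_to_dict(system: SpinSystem) -> dict:
    doc: dict = {"g": list(system.g.values), "nuclei": []}
    if system.name:
        doc["name"] = system.name
    if system.provenance:
        doc["provenance"] = system.provenance
    for entry in system.nuclei:
        rec: dict = {
            "isotope": entry.nucleus.isotope,
            "position": entry.nucleus.position,
            "A": list(entry.hyperfine.values),
        }
        if any(entry.hyperfine.euler):
            rec["A_frame"] = list(entry.hyperfine.euler)
        if entry.quadrupole is not None:
            rec["Q"] = list(entry.quadrupole.values)
            if any(entry.quadrupole.euler):
                rec["Q_frame"] = list(entry.quadrupole.euler)
        doc["nuclei"].append(rec)
    return doc


def _system_from_dict(doc: dict) -> SpinSystem:
    try:
        g = GTensor(*[float(v) for v in doc["g"]])
    except KeyError:
        raise ValidationError("spin-system file missing 'g'") from None
    system = SpinSystem(g=g, name=str(doc.get("name", "")),
                        provenance=str(doc.get("provenance", "")))
    for rec in doc.get("nuclei", []):
        nucleus = Nucleus(
            rec["isotope"], str(rec.get("position", "")),
            spin=rec.get("spin"), g_factor=rec.get("gN"),
        )
        hf = PrincipalTensor(tuple(rec["A"]), tuple(rec.get("A_frame", (0, 0, 0))))
        q = None
        if "Q" in rec:
            if nucleus.spin <= 0.5:
                raise ValidationError(
                    f"{nucleus.isotope}({nucleus.position}) has I=1/2: a quadrupole "
                    "tensor is only defined for I>1/2"
                )
            q = PrincipalTensor(tuple(rec["Q"]), tuple(rec.get("Q_frame", (0, 0, 0))),
                                traceless=True)
        system.add_nucleus(nucleus, hf, q)
    return system


def write_spin_system(system: SpinSystem, path: str | Path) -> None:
    path = Path(path)
    doc = _system_to_dict(system)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    else:
        path.write_text(json.dumps(doc, indent=2) + "\n")


def read_spin_system(path: str | Path) -> SpinSystem:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path} does not contain a spin-system mapping")
    return _system_from_dict(doc)


def write_spectrum1d(spectrum: Spectrum1D, path: str | Path) -> None:
    path = Path(path)
    header = [f"# axis_unit: {spectrum.axis_unit}", f"# kind: {spectrum.kind}"]
    for key, val in sorted(spectrum.meta.items()):
        if isinstance(val, (int, float, str)):
            header.append(f"# {key}: {val}")
    body = "\n".join(
        f"{x:.10g}\t{y:.10g}" for x, y in zip(spectrum.axis, spectrum.amplitude)
    )
    path.write_text("\n".join(header) + "\n" + body + "\n")


def read_spectrum1d(path: str | Path) -> Spectrum1D:
    path = Path(path)
    meta: dict = {}
    axis, amp = [], []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, val = line[1:].split(":", 1)
                meta[key.strip()] = val.strip()
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValidationError(f"malformed spectrum line in {path}: {line!r}")
        axis.append(float(parts[0]))
        amp.append(float(parts[1]))
    if not axis:
        raise ValidationError(f"no data rows in {path}")
    unit = meta.pop("axis_unit", "mT")
    kind = meta.pop("kind", "absorption")
    return Spectrum1D(np.array(axis), np.array(amp), unit, kind, meta)


def write_map2d(map2d: Map2D, path: str | Path) -> None:
    """Write a 2D map as text (.txt/.dat) or HDF5 (.h5/.hdf5)."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            ds = fh.create_dataset("intensity", data=map2d.intensity)
            ds.attrs["axis1_MHz"] = map2d.axis1
            ds.attrs["axis2_MHz"] = map2d.axis2
    else:
        with open(path, "w") as fh:
            fh.write("# axis1_MHz: " + " ".join(f"{v:.10g}" for v in map2d.axis1) + "\n")
            fh.write("# axis2_MHz: " + " ".join(f"{v:.10g}" for v in map2d.axis2) + "\n")
            np.savetxt(fh, map2d.intensity, fmt="%.12e")


def read_map2d(path: str | Path) -> Map2D:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            ds = fh["intensity"]
            axis1 = np.array(ds.attrs["axis1_MHz"])
            axis2 = np.array(ds.attrs["axis2_MHz"])
            intensity = ds[()]
    else:
        axis1 = axis2 = None
        with open(path) as fh:
            lines = fh.readlines()
        rows = []
        for line in lines:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, rest = line[1:].partition(":")
                vals = np.array([float(v) for v in rest.split()])
                if key.strip() == "axis1_MHz":
                    axis1 = vals
                elif key.strip() == "axis2_MHz":
                    axis2 = vals
                continue
            rows.append([float(v) for v in line.split()])
        if axis1 is None or axis2 is None or not rows:
            raise ValidationError(f"{path} is not a valid 2D map file")
        intensity = np.array(rows)
    return Map2D(axis1, axis2, intensity)
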