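"""Structure and trajectory I/O.

Binary/standard formats (GRO, PDB, XTC, TRR) are handled through
MDAnalysis; a versioned plain-JSON trajectory dialect is provided so
tests and fixtures need no binary readers.  All coordinates are
converted to nm and times to ns at this boundary (MDAnalysis uses
Angstrom / ps internally).

JSON trajectory dialect (version 1)
-----------------------------------
::

    {
      "format": "memtk-trajectory",
      "version": 1,
      "atoms": [{"name": "P", "element": "P", "mass": 30.974,
                 "resid": 1, "resname": "POPC"}, ...],
      "molecules": [[0, 1, 2], ...],
      "frames": [{"time_ns": 0.0,
                  "cell_nm": [[...], [...], [...]],
                  "positions_nm": [[x, y, z], ...]}, ...]
    }
"""

from __future__ import annotations

import json
import os
from typing import Iterator

import numpy as np

from memtk.core_model.cell import TriclinicCell
from memtk.core_model.model import ATOMIC_MASSES, Frame, Topology, element_from_name
from memtk.errors import FormatError

JSON_FORMAT_NAME = "memtk-trajectory"
JSON_FORMAT_VERSION = 1

_A_TO_NM = 0.1
_PS_TO_NS = 1e-3


def _cell_from_mda_dimensions(dimensions, path: str) -> TriclinicCell:
    import MDAnalysis.lib.mdamath as mdamath

    if dimensions is None or not np.any(np.asarray(dimensions)[:3] > 0):
        raise FormatError(f"{path}: no periodic box information found")
    vecs = mdamath.triclinic_vectors(dimensions) * _A_TO_NM
    return TriclinicCell(np.asarray(vecs, dtype=float))


def _topology_from_universe(u) -> Topology:
    names = np.array([str(a.name) for a in u.atoms], dtype=object)
    elements = np.array([element_from_name(n) for n in names], dtype=object)
    masses = np.array([ATOMIC_MASSES.get(e, 12.011) for e in elements])
    resids = np.array([int(a.resid) for a in u.atoms])
    resnames = np.array([str(a.resname) for a in u.atoms], dtype=object)
    molecules = [np.asarray(res.atoms.ix, dtype=int) for res in u.residues]
    return Topology(names, elements, masses, resids, resnames, molecules)


def read_structure(path: str) -> tuple[Topology, Frame]:
    """Read a structure file (GRO, PDB, or the JSON dialect).

    Returns the topology and the first frame with coordinates in nm.
    """
    if not os.path.exists(path):
        raise FormatError(f"{path}: file does not exist")
    if path.endswith(".json"):
        topology, frames = _read_json(path)
        if not frames:
            raise FormatError(f"{path}: JSON structure contains no frames")
        return topology, frames[0]

    import MDAnalysis as mda

    try:
        u = mda.Universe(path)
    except Exception as exc:  # MDA raises assorted parse errors
        raise FormatError(f"{path}: could not parse structure ({exc})") from exc
    cell = _cell_from_mda_dimensions(u.dimensions, path)
    topology = _topology_from_universe(u)
    positions = u.atoms.positions * _A_TO_NM
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # MDA "no dt information"
        time = float(getattr(u.trajectory.ts, "time", 0.0) or 0.0) * _PS_TO_NS
    return topology, Frame(time, positions, cell)


def read_trajectory(path: str, topology: Topology) -> Iterator[Frame]:
    """Iterate frames from a trajectory (XTC/TRR via MDAnalysis, or JSON).

    Frames are yielded in file order with per-frame cells; the atom count
    of every frame must match the topology.
    """
    if path.endswith(".json"):
        _, frames = _read_json(path)
        for k, fr in enumerate(frames):
            _check_count(fr, topology, path, k)
            yield fr
        return

    from MDAnalysis import coordinates as mda_coords

    reader_cls = {".xtc": mda_coords.XTC.XTCReader, ".trr": mda_coords.TRR.TRRReader}.get(
        os.path.splitext(path)[1].lower()
    )
    if reader_cls is None:
        raise FormatError(f"{path}: unsupported trajectory format")
    with reader_cls(path) as reader:
        for k, ts in enumerate(reader):
            cell = _cell_from_mda_dimensions(ts.dimensions, path)
            fr = Frame(float(ts.time) * _PS_TO_NS, ts.positions * _A_TO_NM, cell)
            _check_count(fr, topology, path, k)
            yield fr


def _check_count(frame: Frame, topology: Topology, path: str, k: int) -> None:
    if len(frame.positions) != topology.n_atoms:
        raise FormatError(
            f"{path}: frame {k} has {len(frame.positions)} atoms, "
            f"expected {topology.n_atoms}"
        )


# -- JSON dialect ---------------------------------------------------------


def _read_json(path: str) -> tuple[Topology, list[Frame]]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}") from exc
    if doc.get("format") != JSON_FORMAT_NAME:
        raise FormatError(f"{path}: not a {JSON_FORMAT_NAME} file")
    if doc.get("version") != JSON_FORMAT_VERSION:
        raise FormatError(f"{path}: unsupported dialect version {doc.get('version')}")
    atoms = doc["atoms"]
    topology = Topology(
        names=np.array([a["name"] for a in atoms], dtype=object),
        elements=np.array([a["element"] for a in atoms], dtype=object),
        masses=np.array([a["mass"] for a in atoms], dtype=float),
        resids=np.array([a["resid"] for a in atoms], dtype=int),
        resnames=np.array([a["resname"] for a in atoms], dtype=object),
        molecules=[np.asarray(m, dtype=int) for m in doc.get("molecules", [])],
    )
    frames = [
        Frame(
            time=float(f["time_ns"]),
            positions=np.asarray(f["positions_nm"], dtype=float),
            cell=TriclinicCell(np.asarray(f["cell_nm"], dtype=float)),
        )
        for f in doc.get("frames", [])
    ]
    return topology, frames


def write_json_trajectory(path: str, topology: Topology, frames) -> None:
    """Write topology + frames in the JSON dialect (plain text, versioned)."""
    doc = {
        "format": JSON_FORMAT_NAME,
        "version": JSON_FORMAT_VERSION,
        "atoms": [
            {
                "name": str(topology.names[i]),
                "element": str(topology.elements[i]),
                "mass": float(topology.masses[i]),
                "resid": int(topology.resids[i]),
                "resname": str(topology.resnames[i]),
            }
            for i in range(topology.n_atoms)
        ],
        "molecules": [[int(i) for i in mol] for mol in topology.molecules],
        "frames": [
            {
                "time_ns": float(fr.time),
                "cell_nm": fr.cell.vectors.tolist(),
                "positions_nm": np.round(fr.positions, 9).tolist(),
            }
            for fr in frames
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def write_gro(path: str, topology: Topology, frame: Frame) -> None:
    """Write a single frame as a GRO file (via MDAnalysis)."""
    import MDAnalysis as mda
    import MDAnalysis.lib.mdamath as mdamath

    resid_values, resindex = np.unique(topology.resids, return_inverse=True)
    u = mda.Universe.empty(
        n_atoms=topology.n_atoms,
        n_residues=len(resid_values),
        atom_resindex=resindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in topology.names])
    u.add_TopologyAttr("resids", [int(r) for r in resid_values])
    resname_by_resid = {}
    for rid, rn in zip(topology.resids, topology.resnames):
        resname_by_resid.setdefault(int(rid), str(rn))
    u.add_TopologyAttr("resnames", [resname_by_resid[int(r)] for r in resid_values])
    u.atoms.positions = frame.positions / _A_TO_NM
    u.dimensions = mdamath.triclinic_box(*(frame.cell.vectors / _A_TO_NM))
    u.atoms.write(path)
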