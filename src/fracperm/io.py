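"""Plain-text I/O for profiles, windows, trajectories and structures.

Dialects (all whitespace-delimited, ``#`` comments):

* profile files — two columns ``z value``; the header carries a units tag
  and optional ``key=value`` metadata;
* window files — three columns ``z n g`` (bin centre Å, force-sample
  count, mean gradient kcal/mol/Å), one file per stratification window;
* trajectory files — columns ``t z [x y]`` with t in ps and coordinates
  in Å (converted to the ns-based internal representation);
* structures — PDB (cell from CRYST1) via biotite, or XYZ plus an explicit
  cell; atomic radii from a two-column ``type radius`` table.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .profiles import GradientWindow, Profile
from .synth import AtomicConfiguration
from .trajectory import Trajectory

__all__ = [
    "read_profile", "write_profile", "read_window", "write_window",
    "read_trajectory", "write_trajectory", "read_structure",
    "read_radius_table", "write_result_json",
]


def read_profile(path) -> Profile:
    units = ""
    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("units:"):
                    units = body.split(":", 1)[1].strip()
                elif "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
    z, v = np.loadtxt(path, unpack=True, comments="#")
    return Profile.from_z(z, v, units, **meta)


def write_profile(path, profile: Profile, comment: str = ""):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"# units: {profile.units}\n")
        for k, v in profile.meta.items():
            fh.write(f"# {k} = {v}\n")
        for z, v in zip(profile.z, profile.values):
            fh.write(f"{z:.6f} {v:.10g}\n")


def read_window(path, window_id=None) -> GradientWindow:
    z, n, g = np.loadtxt(path, unpack=True, comments="#")
    bw = float(np.median(np.diff(z)))
    return GradientWindow(window_id or Path(path).stem,
                          float(z[0]) - bw / 2, float(z[-1]) + bw / 2,
                          bw, n, np.nan_to_num(g))


def write_window(path, w: GradientWindow, comment: str = ""):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write("# z  n  g(kcal/mol/Å)\n")
        for z, n, g in zip(w.centers, w.n, w.g):
            fh.write(f"{z:.6f} {n:.10g} {g:.10g}\n")


def read_trajectory(path) -> Trajectory:
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("trajectory file needs columns t z [x y]")
    t_ps = data[:, 0]
    dts = np.diff(t_ps)
    if dts.size == 0 or not np.allclose(dts, dts[0], rtol=1e-5, atol=1e-9):
        raise ValueError("trajectory must be uniformly sampled")
    dt_ns = float(dts[0]) * 1e-3
    x = data[:, 2] if data.shape[1] > 2 else None
    y = data[:, 3] if data.shape[1] > 3 else None
    return Trajectory(dt_ns, data[:, 1], x, y,
                      meta={"source": str(path)})


def write_trajectory(path, tr: Trajectory, comment: str = ""):
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        for k, v in tr.meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# t(ps)  z(Å)" + ("  x(Å)" if tr.x is not None else "")
                 + ("  y(Å)" if tr.y is not None else "") + "\n")
        t_ps = tr.t * 1e3
        cols = [t_ps, tr.z] + [c for c in (tr.x, tr.y) if c is not None]
        for row in zip(*cols):
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_radius_table(path) -> dict:
    table = {}
    with open(path) as fh:
        for line in fh:
            body = line.split("#")[0].strip()
            if not body:
                continue
            name, r = body.split()[:2]
            table[name] = float(r)
    return table


def read_structure(path, radii: dict, cell=None) -> AtomicConfiguration:
    """Load a PDB or XYZ configuration for void analysis.

    PDB cells come from the CRYST1 record (orthorhombic only); XYZ files
    need an explicit ``cell``.  ``radii`` maps atom type/element to the
    R_min/2 sphere radius (Å).
    """
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        from biotite.structure.io.pdb import PDBFile

        pdb = PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1)
        box = atoms.box
        if cell is None:
            if box is None:
                raise ValueError("PDB lacks CRYST1; pass cell explicitly")
            if not np.allclose(box, np.diag(np.diag(box)), atol=1e-3):
                raise ValueError("only orthorhombic cells are supported")
            cell = np.diag(box)
        types = [e if e else n[0] for e, n in
                 zip(atoms.element, atoms.atom_name)]
        return AtomicConfiguration(atoms.coord, types, radii, cell)
    if path.suffix.lower() == ".xyz":
        if cell is None:
            raise ValueError("XYZ input requires an explicit cell")
        with open(path) as fh:
            n = int(fh.readline())
            fh.readline()
            types, coords = [], []
            for _ in range(n):
                parts = fh.readline().split()
                types.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
        return AtomicConfiguration(np.array(coords), types, radii, cell)
    raise ValueError(f"unsupported structure format: {path.suffix}")


def write_result_json(path, payload: dict):
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
        fh.write("\n")
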