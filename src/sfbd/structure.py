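"""Molecular structures and file I/O (Tinker-dialect XYZ, plain-text Hessians).

The Tinker XYZ dialect is: a header line with the atom count (and an optional
title), then one line per atom with ``index  element  x  y  z  type  bonded
indices...`` (coordinates in angstroms, indices 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KCAL_PER_MOL


@dataclass
class CartesianStructure:
    """Atoms with Cartesian coordinates (angstrom) and bond connectivity."""

    elements: list[str]
    coords: np.ndarray  # (N, 3), angstrom
    bonds: list[tuple[int, int]] = field(default_factory=list)  # 0-based pairs
    atom_types: list[int] | None = None
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if len(self.elements) != self.coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        self.bonds = [tuple(sorted((int(i), int(j)))) for i, j in self.bonds]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def adjacency(self) -> list[set[int]]:
        adj: list[set[int]] = [set() for _ in range(self.n_atoms)]
        for i, j in self.bonds:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def is_connected(self) -> bool:
        if self.n_atoms == 0:
            return False
        adj = self.adjacency()
        seen = {0}
        stack = [0]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_atoms


def read_tinker_xyz(path) -> CartesianStructure:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split()
    n = int(header[0])
    title = " ".join(header[1:])
    elements, coords, types = [], [], []
    bonds: list[tuple[int, int]] = []
    for ln in lines[1 : 1 + n]:
        parts = ln.split()
        idx = int(parts[0]) - 1
        elements.append(parts[1])
        coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
        types.append(int(parts[5]) if len(parts) > 5 else 0)
        for b in parts[6:]:
            j = int(b) - 1
            if j > idx:
                bonds.append((idx, j))
            else:
                bonds.append((j, idx))
    return CartesianStructure(
        elements=elements,
        coords=np.array(coords),
        bonds=sorted(set(bonds)),
        atom_types=types,
        title=title,
    )


def write_tinker_xyz(structure: CartesianStructure, path, coords=None) -> None:
    """Write a structure; ``coords`` (n_frames, N, 3) writes a multi-frame file."""
    frames = structure.coords[None] if coords is None else np.atleast_3d(coords)
    if frames.ndim == 2:
        frames = frames[None]
    adj = structure.adjacency()
    types = structure.atom_types or [0] * structure.n_atoms
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{structure.n_atoms:6d}  {structure.title}\n")
            for i in range(structure.n_atoms):
                nbrs = " ".join(f"{j + 1:5d}" for j in sorted(adj[i]))
                x, y, z = frame[i]
                fh.write(
                    f"{i + 1:6d}  {structure.elements[i]:<3s}"
                    f"{x:12.6f}{y:12.6f}{z:12.6f}{types[i]:6d} {nbrs}\n"
                )


def read_hessian(path) -> np.ndarray:
    """Read a dense Cartesian Hessian and convert to J/angstrom^2 per molecule.

    Plain-text format: optional comment/header lines starting with '#', one of
    which may declare ``# units: kcal/mol/A^2`` (the Tinker convention, default)
    or ``# units: J/A^2``; then the 3N x 3N matrix, whitespace separated.
    HDF5 files (suffix .h5/.hdf5) must contain a dataset ``hessian`` and may
    carry a ``units`` attribute with the same two values.
    """
    spath = str(path)
    units = "kcal/mol/A^2"
    if spath.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(spath, "r") as fh:
            dset = fh["hessian"]
            units = dset.attrs.get("units", units)
            if isinstance(units, bytes):
                units = units.decode()
            H = np.asarray(dset, dtype=float)
    else:
        rows = []
        with open(spath) as fh:
            for ln in fh:
                s = ln.strip()
                if not s:
                    continue
                if s.startswith("#"):
                    if "units:" in s:
                        units = s.split("units:", 1)[1].strip()
                    continue
                rows.append([float(tok) for tok in s.split()])
        H = np.array(rows, dtype=float)
    if H.ndim != 2 or H.shape[0] != H.shape[1] or H.shape[0] % 3:
        raise ValueError(f"Hessian must be square 3Nx3N, got {H.shape}")
    key = units.lower().replace(" ", "")
    if key in ("kcal/mol/a^2", "kcal/mol/ang^2", "kcalmol-1a-2"):
        return H * KCAL_PER_MOL
    if key in ("j/a^2", "j/ang^2"):
        return H
    raise ValueError(f"unknown Hessian units: {units!r}")


def write_hessian(H_joule: np.ndarray, path, units: str = "kcal/mol/A^2") -> None:
    H = np.asarray(H_joule, dtype=float)
    if units.lower().replace(" ", "") in ("kcal/mol/a^2",):
        out = H / KCAL_PER_MOL
    elif units.lower().replace(" ", "") in ("j/a^2",):
        out = H
    else:
        raise ValueError(f"unknown Hessian units: {units!r}")
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        for row in out:
            fh.write(" ".join(f"{v: .16e}" for v in row) + "\n")
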