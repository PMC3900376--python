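"""Extended-XYZ trajectory reading and writing (coordinates in nm).

The dialect written here is the widely used extxyz flavour: an atom
count line, a comment line carrying ``Properties=species:S:1:pos:R:3``
and optionally ``Lattice="ax 0 0 0 by 0 0 0 cz"`` for orthorhombic
boxes, then one ``species x y z`` line per atom.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .types import Frame


class XYZParseError(ValueError):
    pass


def write_xyz_trajectory(
    frames: Sequence[Frame], species: Sequence[str], path
) -> None:
    with open(path, "w") as fh:
        for frame in frames:
            if frame.n_atoms != len(species):
                raise XYZParseError("species list does not match frame atom count")
            fh.write(f"{frame.n_atoms}\n")
            comment = "Properties=species:S:1:pos:R:3"
            if frame.box is not None:
                a, b, c = frame.box
                comment += f' Lattice="{a:.8f} 0 0 0 {b:.8f} 0 0 0 {c:.8f}"'
            fh.write(comment + "\n")
            for name, xyz in zip(species, frame.coordinates):
                fh.write(f"{name} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


def read_xyz_trajectory(path) -> List[Frame]:
    frames: List[Frame] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(f"line {pos + 1}: expected atom count")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        box: Optional[np.ndarray] = None
        if "Lattice=" in comment:
            lattice = comment.split('Lattice="')[1].split('"')[0].split()
            mat = np.array([float(v) for v in lattice]).reshape(3, 3)
            box = np.diag(mat)
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[pos + 2 + k].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {pos + 3 + k}: expected 'species x y z'")
            coords[k] = [float(v) for v in parts[1:4]]
        frames.append(Frame(coords, box=box))
        pos += 2 + n
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return frames
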