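"""Extended-XYZ trajectory output (plain text, one frame per snapshot).

Per-atom columns: species (``B`` body / ``P`` adhesin), molecule (cell) id,
Cartesian position.  The comment line carries the box as a ``Lattice``
matrix, a ``Properties`` descriptor, and the frame time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_frames", "read_frames"]

_PROPS = "Properties=species:S:1:mol:I:1:pos:R:3"


def _frame_lines(state, template) -> list[str]:
    N = state.n_cells
    na = template.n_adhesins
    adh = state.adhesin_world_coords(template)
    box = state.box
    lines = [str(N * (na + 1))]
    lattice = f"{box[0]:.10g} 0 0 0 {box[1]:.10g} 0 0 0 {box[2]:.10g}"
    lines.append(f'Lattice="{lattice}" {_PROPS} Time={state.time:.10g}')
    for i in range(N):
        p = state.positions[i]
        lines.append(f"B {i} {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}")
        for k in range(na):
            q = adh[i, k]
            lines.append(f"P {i} {q[0]:.8f} {q[1]:.8f} {q[2]:.8f}")
    return lines


def write_frames(path, states, template) -> None:
    """Write an extended-XYZ file with one frame per state."""
    with open(path, "w") as fh:
        for state in states:
            fh.write("\n".join(_frame_lines(state, template)) + "\n")


def read_frames(path) -> list[dict]:
    """Read extended-XYZ frames back as dicts.

    Each frame dict has ``species`` (array of 'B'/'P'), ``mol`` (cell ids),
    ``positions`` (n_atoms, 3), ``box`` (3,) and ``time``.
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n_atoms = int(lines[i].strip())
        header = lines[i + 1]
        box = np.full(3, np.inf)
        if 'Lattice="' in header:
            lat = header.split('Lattice="')[1].split('"')[0].split()
            m = np.array(lat, dtype=float).reshape(3, 3)
            box = np.diag(m)
        time = 0.0
        for tok in header.split():
            if tok.startswith("Time="):
                time = float(tok[5:])
        species = np.empty(n_atoms, dtype="U1")
        mol = np.empty(n_atoms, dtype=np.int64)
        pos = np.empty((n_atoms, 3))
        for k in range(n_atoms):
            parts = lines[i + 2 + k].split()
            species[k] = parts[0]
            mol[k] = int(parts[1])
            pos[k] = [float(parts[2]), float(parts[3]), float(parts[4])]
        frames.append(
            {"species": species, "mol": mol, "positions": pos, "box": box, "time": time}
        )
        i += 2 + n_atoms
    return frames
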