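"""openCARP-dialect mesh IO and per-node data files.

``.pts`` holds a node-count header then xyz per line (micrometres);
``.elem`` holds an element-count header then ``Tt n0 n1 n2 n3 label``
lines; ``.lon`` holds one fiber (or fiber+sheet) vector per element.
Activation and repolarization maps are written as plain ``.dat`` files,
one value per line, in node order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import VolumetricMesh

UM_PER_MM = 1000.0


def write_carp(mesh: VolumetricMesh, basename) -> None:
    """Write ``<basename>.pts/.elem/.lon`` (coordinates in micrometres)."""
    base = Path(basename)
    base.parent.mkdir(parents=True, exist_ok=True)
    pts = mesh.nodes * UM_PER_MM
    with open(base.with_suffix(".pts"), "w") as f:
        f.write(f"{len(pts)}\n")
        for x, y, z in pts:
            f.write(f"{x:.3f} {y:.3f} {z:.3f}\n")
    with open(base.with_suffix(".elem"), "w") as f:
        f.write(f"{mesh.n_elements}\n")
        for (a, b, c, d), lab in zip(mesh.elements, mesh.element_labels):
            f.write(f"Tt {a} {b} {c} {d} {lab}\n")
    with open(base.with_suffix(".lon"), "w") as f:
        f.write("2\n")
        if mesh.element_fibers is None:
            for _ in range(mesh.n_elements):
                f.write("1 0 0 0 1 0\n")
        else:
            for frame in mesh.element_fibers:
                fb, sh = frame[0], frame[1]
                f.write(f"{fb[0]:.6f} {fb[1]:.6f} {fb[2]:.6f} "
                        f"{sh[0]:.6f} {sh[1]:.6f} {sh[2]:.6f}\n")


def read_carp(basename) -> VolumetricMesh:
    """Read a ``.pts/.elem/.lon`` triple written by :func:`write_carp`."""
    base = Path(basename)
    with open(base.with_suffix(".pts")) as f:
        n = int(f.readline())
        nodes = np.loadtxt(f, max_rows=n, ndmin=2) / UM_PER_MM
    if len(nodes) != n:
        raise ValueError(f".pts header promises {n} nodes, found {len(nodes)}")

    elements, labels = [], []
    with open(base.with_suffix(".elem")) as f:
        m = int(f.readline())
        for lineno, line in enumerate(f, start=2):
            tok = line.split()
            if not tok:
                continue
            if tok[0] != "Tt" or len(tok) != 6:
                raise ValueError(
                    f"{base.with_suffix('.elem')}:{lineno}: unsupported "
                    f"element token {tok[0]!r} (expected 'Tt')")
            elements.append([int(t) for t in tok[1:5]])
            labels.append(int(tok[5]))
    if len(elements) != m:
        raise ValueError(f".elem header promises {m} elements, "
                         f"found {len(elements)}")

    fibers = None
    lon = base.with_suffix(".lon")
    if lon.exists():
        with open(lon) as f:
            per_line = int(f.readline())
            arr = np.loadtxt(f, ndmin=2)
        if per_line >= 2 and arr.shape[1] >= 6:
            fb = arr[:, 0:3]
            sh = arr[:, 3:6]
            nr = np.cross(fb, sh)
            fibers = np.stack([fb, sh, nr], axis=1)
    return VolumetricMesh(nodes=nodes,
                          elements=np.asarray(elements, dtype=np.int64),
                          element_labels=np.asarray(labels, dtype=np.int16),
                          element_fibers=fibers)


def write_dat(values, path) -> None:
    """Per-node scalar field, one value per line (openCARP .dat)."""
    np.savetxt(path, np.asarray(values, float), fmt="%.6f")


def read_dat(path) -> np.ndarray:
    return np.loadtxt(path, dtype=float)
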