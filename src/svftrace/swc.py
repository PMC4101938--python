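"""SWC morphology export and import.

SWC is the standard plain-text neuron-morphology format: one sample per
line, ``index type x y z radius parent``, with parent ``-1`` for the root.
svftrace stores points as ``(z, y, x)``; SWC columns are written in
``x y z`` order.  Floats are written with fixed precision so repeated runs
produce byte-identical files.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError
from .snake import NeuronTrace

__all__ = ["write_swc", "read_swc"]

_TYPE_CODE = 0  # undefined neurite type


def write_swc(path, trace: NeuronTrace) -> None:
    """Serialize a trace: each curve is a chain; links attach child chains.

    A linked child curve is oriented so its attaching end comes first and its
    first sample's parent is the attachment node on the parent curve.
    """
    parent_map = {c: (p, j, e) for c, p, j, e in trace.links}
    node_id = {}
    lines = []
    next_id = 1

    order = _emit_order(trace, parent_map)
    for ci in order:
        curve = trace.curves[ci]
        pts = curve.points
        radii = curve.radii
        if ci in parent_map:
            p, j, end = parent_map[ci]
            if end == 1:  # attaching end is the tail: reverse so it comes first
                pts = pts[::-1]
                radii = radii[::-1]
            parent_node = node_id[(p, parent_map[ci][1])]
        else:
            parent_node = -1
        for k in range(len(pts)):
            z, y, x = pts[k]
            lines.append(
                f"{next_id} {_TYPE_CODE} {x:.3f} {y:.3f} {z:.3f} {radii[k]:.3f} "
                f"{parent_node if k == 0 else next_id - 1}"
            )
            # record ids against the curve's original point indexing
            orig_k = len(pts) - 1 - k if (ci in parent_map and parent_map[ci][2] == 1) else k
            node_id[(ci, orig_k)] = next_id
            next_id += 1
    with open(path, "w") as fh:
        fh.write("# SWC generated by svftrace\n")
        fh.write("# index type x y z radius parent\n")
        for line in lines:
            fh.write(line + "\n")


def _emit_order(trace: NeuronTrace, parent_map) -> list[int]:
    """Parents before children (roots first, then breadth-first)."""
    order, seen = [], set()
    pending = [ci for ci in range(len(trace.curves)) if ci not in parent_map]
    while pending:
        ci = pending.pop(0)
        if ci in seen:
            continue
        seen.add(ci)
        order.append(ci)
        pending.extend(c for c, (p, _, _) in parent_map.items() if p == ci)
    order.extend(ci for ci in range(len(trace.curves)) if ci not in seen)
    return order


def read_swc(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read an SWC file.

    Returns ``(points, radii, parents)`` where points are ``(n, 3)`` in
    ``(z, y, x)`` order and parents are 0-based indices (-1 for roots).
    """
    ids, pts, radii, parents = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 7:
                raise FormatError(f"{path}:{lineno}: expected 7 SWC columns, got {len(cols)}")
            ids.append(int(cols[0]))
            x, y, z = float(cols[2]), float(cols[3]), float(cols[4])
            pts.append((z, y, x))
            radii.append(float(cols[5]))
            parents.append(int(cols[6]))
    id_to_row = {i: r for r, i in enumerate(ids)}
    par = np.array([id_to_row[p] if p != -1 else -1 for p in parents], dtype=int)
    return np.asarray(pts), np.asarray(radii), par
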