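"""Export of per-voxel orientation glyphs as legacy-VTK ASCII polydata.

Each valid voxel in the selected slice(s) becomes one line cell along the
tertiary eigenvector, centred on the voxel, with the helical angle
attached as a point scalar (``HA_deg``) — ready for a ParaView tube
filter colour-coded by HA.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["export_glyphs"]


def export_glyphs(path: str | Path, v3: np.ndarray, ha: np.ndarray,
                  valid: np.ndarray, voxel_size_um: float | tuple,
                  z_slices: int | slice | np.ndarray | None = None,
                  scale_um: float | None = None) -> int:
    """Write one line glyph per selected valid voxel; returns the count.

    ``z_slices`` selects sectioning planes (an int, a slice, or an index
    array; None = all). ``scale_um`` is the glyph length (default: two
    voxel sizes).
    """
    valid = np.asarray(valid, bool)
    vs = np.broadcast_to(np.atleast_1d(voxel_size_um), (3,)).astype(float)
    sel = np.zeros_like(valid)
    if z_slices is None:
        sel[:] = valid
    else:
        sel[:, :, z_slices] = valid[:, :, z_slices]
    idx = np.argwhere(sel)
    if len(idx) == 0:
        raise ValueError("empty glyph selection: no valid voxels in the "
                         "requested slices")
    if scale_um is None:
        scale_um = 2.0 * float(vs.min())
    centres = idx * vs
    dirs = np.asarray(v3)[sel].astype(float)
    ha_vals = np.asarray(ha)[sel].astype(float)
    half = 0.5 * scale_um * dirs
    p0 = centres - half
    p1 = centres + half
    n = len(idx)
    lines = [
        "# vtk DataFile Version 3.0",
        "myoarch orientation glyphs (µm, scalar = helical angle in degrees)",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {2 * n} float",
    ]
    pts = np.empty((2 * n, 3))
    pts[0::2] = p0
    pts[1::2] = p1
    lines += [" ".join(f"{v:.4f}" for v in p) for p in pts]
    lines.append(f"LINES {n} {3 * n}")
    lines += [f"2 {2 * i} {2 * i + 1}" for i in range(n)]
    lines.append(f"POINT_DATA {2 * n}")
    lines.append("SCALARS HA_deg float 1")
    lines.append("LOOKUP_TABLE default")
    ha_rep = np.repeat(ha_vals, 2)
    lines += [f"{v:.4f}" for v in ha_rep]
    Path(path).write_text("\n".join(lines) + "\n")
    return n
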