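"""ESRI ASCII grid reader/writer.

Grids are stored in memory as 2-D arrays with row 0 at the *south* edge
(matching the local planar coordinate system, origin at the southwest
corner).  The .asc format stores the north row first, so rows are flipped
on read and write.
"""

from __future__ import annotations

import numpy as np

NODATA = -9999.0


def write_asc(path, values: np.ndarray, xllcorner: float, yllcorner: float,
              cellsize: float, nodata: float = NODATA) -> None:
    """Write a south-row-first 2-D array as an ESRI ASCII grid."""
    values = np.asarray(values, dtype=float)
    ny, nx = values.shape
    out = np.where(np.isnan(values), nodata, values)
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {xllcorner:.6f}\n")
        fh.write(f"yllcorner {yllcorner:.6f}\n")
        fh.write(f"cellsize {cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:.6f}\n")
        for row in out[::-1]:  # north row first
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_asc(path):
    """Read an ESRI ASCII grid; returns (values, xllcorner, yllcorner, cellsize).

    NODATA cells come back as NaN; the returned array has row 0 at the
    south edge.
    """
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"):
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    nodata = header.get("nodata_value", NODATA)
    values = np.loadtxt(lines[i:], dtype=float)
    values = np.atleast_2d(values)[::-1].copy()
    values[values == nodata] = np.nan
    assert values.shape == (int(header["nrows"]), int(header["ncols"]))
    return values, header["xllcorner"], header["yllcorner"], header["cellsize"]
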