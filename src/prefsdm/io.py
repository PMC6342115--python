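"""Readers and writers for the package's plain-text formats.

* Point tables: comma-separated with header ``x,y,mark[,covariate]``;
  coordinates are real-valued in grid units and map to 0-based cell
  indices by floor division against the grid origin and cell size.
* Surfaces: ESRI ASCII grid (.asc) — a 6-line header (ncols, nrows,
  xllcorner, yllcorner, cellsize, NODATA_value) followed by rows written
  north-to-south.  Round-trips are bit-exact (values are written with
  ``repr`` precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError
from .grids import GridGeometry, LatentField
from .sampling import MarkedSample, SampleDesign

_NODATA = -9999.0


def write_points(sample: MarkedSample, path, sidecar: bool = True) -> None:
    """Write a point table; optionally a ``.design`` sidecar with metadata."""
    df = pd.DataFrame({"x": sample.coords[:, 0], "y": sample.coords[:, 1], "mark": sample.marks})
    if sample.covariate is not None:
        df["covariate"] = sample.covariate
    df.to_csv(path, index=False)
    if sidecar:
        d = sample.design
        lines = [
            "[design]",
            f"kind = {d.kind}",
            f"n = {d.n}",
            f"preferentiality = {d.preferentiality!r}",
            f"with_replacement = {d.with_replacement}",
        ]
        for key, value in sample.obs_params.items():
            lines.append(f"{key} = {value!r}")
        Path(str(path) + ".design").write_text("\n".join(lines) + "\n")


def read_design_sidecar(path) -> SampleDesign | None:
    """Design metadata for a point table, if its sidecar exists."""
    import configparser

    sidecar = Path(str(path) + ".design")
    if not sidecar.exists():
        return None
    parser = configparser.ConfigParser()
    parser.read_string(sidecar.read_text())
    d = parser["design"]
    return SampleDesign(
        kind=d.get("kind", "uniform"),
        n=d.getint("n", 1),
        preferentiality=d.getfloat("preferentiality", 0.0),
        with_replacement=d.getboolean("with_replacement", True),
    )


def read_points(path, grid: GridGeometry) -> MarkedSample:
    """Parse a delimited point table into a MarkedSample on ``grid``.

    Validates coordinates against the grid; positivity of gamma-family
    marks is deferred to fit time.  Parse errors name the offending line
    (1-based, header is line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error variety
        raise FormatError(f"{path}: cannot parse as CSV: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    for required in ("x", "y", "mark"):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")
    parsed = {}
    for col in ("x", "y", "mark") + (("covariate",) if "covariate" in cols else ()):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.index[values.isna() & df[col].notna()]
        if len(bad):
            line = int(bad[0]) + 2  # header occupies line 1
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {line}")
        if values.isna().any():
            line = int(values.index[values.isna()][0]) + 2
            raise FormatError(f"{path}: empty value in column {col!r} at line {line}")
        parsed[col] = values.to_numpy(dtype=float)
    n = len(df)
    if n == 0:
        return MarkedSample(
            grid=grid,
            cells=np.empty(0, dtype=int),
            marks=np.empty(0),
            design=SampleDesign(kind="uniform", n=1),
        )
    cells = grid.cell_of_coords(parsed["x"], parsed["y"])
    design = read_design_sidecar(path) or SampleDesign(kind="uniform", n=n)
    return MarkedSample(
        grid=grid,
        cells=cells,
        marks=parsed["mark"],
        design=design,
        covariate=parsed.get("covariate"),
    )


def write_grid(surface: LatentField, path, nodata: float = _NODATA) -> None:
    """Write a surface as an ESRI ASCII grid (rows north-to-south)."""
    g = surface.grid
    values = surface.as_array()  # (ny, nx), row 0 at the south edge
    lines = [
        f"ncols {g.nx}",
        f"nrows {g.ny}",
        f"xllcorner {float(g.origin[0])!r}",
        f"yllcorner {float(g.origin[1])!r}",
        f"cellsize {float(g.cell_size)!r}",
        f"NODATA_value {float(nodata)!r}",
    ]
    out = np.where(np.isnan(values), nodata, values)
    for iy in range(g.ny - 1, -1, -1):  # north first
        lines.append(" ".join(repr(float(v)) for v in out[iy]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_grid(path) -> LatentField:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if len(text) < 7:
        raise FormatError(f"{path}: truncated ESRI ASCII grid (needs 6 header lines + data)")
    header = {}
    for i, key in enumerate(("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")):
        parts = text[i].split()
        if len(parts) != 2 or parts[0].lower() != key:
            raise FormatError(f"{path}: header line {i + 1} should be '{key} <value>'")
        header[key] = float(parts[1])
    nx, ny = int(header["ncols"]), int(header["nrows"])
    rows = []
    for j, line in enumerate(text[6:]):
        vals = line.split()
        if len(vals) != nx:
            raise FormatError(f"{path}: data row {j + 1} has {len(vals)} values, expected {nx}")
        rows.append([float(v) for v in vals])
    if len(rows) != ny:
        raise FormatError(f"{path}: {len(rows)} data rows, expected {ny}")
    arr = np.array(rows[::-1])  # back to south-first storage
    arr[arr == header["nodata_value"]] = np.nan
    grid = GridGeometry(
        nx=nx,
        ny=ny,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
    )
    values = arr.ravel()
    finite = np.where(np.isfinite(values), values, 0.0)
    field = LatentField(grid, finite, {"source": str(path)})
    field.values = values  # restore NaN for NODATA after validation of shape
    return field
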