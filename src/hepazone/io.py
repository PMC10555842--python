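"""Readers and writers for the pipeline's plain-text formats.

Formats (all documented minimal dialects):

* **Report TSV** — long-format precursor x channel table with columns
  Run, Protein.Group, Precursor.Id, Channel, Ms1.Area,
  Fragment.Quant.Raw (semicolon-separated non-negative numbers),
  Lib.PG.Q.Value, Q.Value, Channel.Q.Value.
* **Protein matrix** — wide CSV, rows = protein groups, columns =
  sample ids, empty cells = missing; optional samples sidecar CSV.
* **Cells CSV** — cell_id, run, channel, centroid_x, centroid_y,
  area_um2, d_pv_um, d_cv_um.
* **Contour XML** — a minimal laser-microdissection flavoured schema:
  ``<ShapeList>`` with ``<CalibrationPoints>`` and one ``<Shape>`` per
  cell holding ``<Point x= y=>`` elements in 0-based pixel coordinates
  (y increases downward).

Every writer produces files its paired reader parses losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree

from .imaging import Contour

__all__ = [
    "REPORT_COLUMNS",
    "read_report",
    "write_report",
    "read_matrix",
    "write_matrix",
    "read_cells",
    "write_cells",
    "read_contours_xml",
    "write_contours_xml",
    "read_contours_csv",
    "write_contours_csv",
]

REPORT_COLUMNS = (
    "Run", "Protein.Group", "Precursor.Id", "Channel", "Ms1.Area",
    "Fragment.Quant.Raw", "Lib.PG.Q.Value", "Q.Value", "Channel.Q.Value",
)

CELLS_COLUMNS = (
    "cell_id", "run", "channel", "centroid_x", "centroid_y",
    "area_um2", "d_pv_um", "d_cv_um",
)


def read_report(path: str | Path) -> pd.DataFrame:
    """Read a precursor report TSV; validates columns and fragment syntax.

    Malformed fragment strings are rejected with their 1-based data line
    number.
    """
    df = pd.read_csv(path, sep="\t", dtype={"Run": str, "Protein.Group": str, "Precursor.Id": str})
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report {path} is missing required column(s): {', '.join(missing)}")
    for lineno, raw in enumerate(df["Fragment.Quant.Raw"], start=1):
        try:
            values = [float(x) for x in str(raw).split(";") if x != ""]
        except ValueError as err:
            raise ValueError(f"line {lineno}: malformed Fragment.Quant.Raw {raw!r}") from err
        if any(v < 0 for v in values):
            raise ValueError(f"line {lineno}: negative fragment intensity in {raw!r}")
    df["Channel"] = df["Channel"].astype(int)
    return df


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t", index=False)


def read_matrix(path: str | Path, samples_path: str | Path | None = None):
    """Read a wide protein x sample CSV (and optional samples sidecar)."""
    matrix = pd.read_csv(path, index_col=0)
    if samples_path is not None:
        samples = pd.read_csv(samples_path, index_col=0)
        return matrix, samples
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 samples: pd.DataFrame | None = None,
                 samples_path: str | Path | None = None) -> None:
    matrix.to_csv(path)
    if samples is not None:
        if samples_path is None:
            p = Path(path)
            samples_path = p.with_name(p.stem + ".samples.csv")
        samples.to_csv(samples_path)


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    """Write the per-cell metadata CSV in the canonical column layout."""
    out = pd.DataFrame({
        "cell_id": cells.index,
        "run": cells["run"].values,
        "channel": cells["channel"].values,
        "centroid_x": cells["x"].values,
        "centroid_y": cells["y"].values,
        "area_um2": cells["area_um2"].values,
        "d_pv_um": cells["d_pv"].values,
        "d_cv_um": cells["d_cv"].values,
    })
    out.to_csv(path, index=False)


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "run": str})
    missing = [c for c in CELLS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cells file {path} is missing column(s): {', '.join(missing)}")
    df = df.rename(columns={
        "centroid_x": "x", "centroid_y": "y", "d_pv_um": "d_pv", "d_cv_um": "d_cv",
    })
    return df.set_index("cell_id")


def write_contours_xml(
    contours: dict[str, Contour],
    path: str | Path,
    calibration_points: list[tuple[float, float]] | None = None,
) -> None:
    root = etree.Element("ShapeList")
    cal = etree.SubElement(root, "CalibrationPoints")
    for x, y in calibration_points or []:
        etree.SubElement(cal, "Point", x=repr(float(x)), y=repr(float(y)))
    for cell_id, contour in contours.items():
        shape = etree.SubElement(root, "Shape", id=str(cell_id),
                                 pixel_size_um=repr(float(contour.pixel_size_um)))
        for x, y in contour.vertices:
            etree.SubElement(shape, "Point", x=repr(float(x)), y=repr(float(y)))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8"))


def read_contours_xml(path: str | Path) -> tuple[dict[str, Contour], list[tuple[float, float]]]:
    tree = etree.parse(str(path))
    root = tree.getroot()
    calibration = [
        (float(p.get("x")), float(p.get("y")))
        for p in root.findall("CalibrationPoints/Point")
    ]
    contours = {}
    for shape in root.findall("Shape"):
        points = np.array(
            [[float(p.get("x")), float(p.get("y"))] for p in shape.findall("Point")]
        )
        contours[shape.get("id")] = Contour(points, float(shape.get("pixel_size_um", "1.0")))
    return contours, calibration


def write_contours_csv(contours: dict[str, Contour], path: str | Path) -> None:
    rows = []
    for cell_id, contour in contours.items():
        for i, (x, y) in enumerate(contour.vertices):
            rows.append({"cell_id": cell_id, "vertex": i, "x": x, "y": y,
                         "pixel_size_um": contour.pixel_size_um})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_contours_csv(path: str | Path) -> dict[str, Contour]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    contours = {}
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("vertex")
        contours[cell_id] = Contour(
            grp[["x", "y"]].to_numpy(dtype=float),
            float(grp["pixel_size_um"].iloc[0]),
        )
    return contours
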