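"""Readers and writers for the on-disk formats.

Geometry travels as legacy ASCII VTK polydata (a plain-text format that
round-trips bit-stably) or as PLY/STL meshes via trimesh:

* vascular trees: POINTS holds the centreline points followed by the
  bifurcation points; LINES cells are the branch polylines; VERTICES cells
  mark the bifurcation points.
* surfaces: POINTS + POLYGONS triangles, with per-vertex scalar arrays
  (``visible``, and ``R_U_mm`` for uniqueness maps; -1 encodes "not unique
  at the maximum radius").
* bare point sets: POINTS with no (or only VERTICES) cells.

Tables use UTF-8 CSV with a header row and dot decimals; 4x4 matrices are
row-major.  Tracked sweeps live in a directory: ``frames/NNNN.png`` binary
masks, ``poses.csv`` (frame index + 16 matrix values), ``meta.json`` (pixel
spacing in mm and a 4x4 probe calibration), ``digitised_surface.csv`` and
``landmarks_lus.csv`` / ``landmarks_ct.csv``.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import trimesh

from .geometry import PointSet, RigidTransform, SurfaceMesh, VascularTree
from .sweep import SweepFrame, TrackedSweep, TreCurve

__all__ = [
    "read_polydata",
    "write_polydata",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_sweep_dir",
    "write_sweep_dir",
    "write_report",
    "read_report",
]


# ---------------------------------------------------------------------------
# legacy ASCII VTK polydata
# ---------------------------------------------------------------------------


def _fmt_floats(arr: np.ndarray) -> str:
    return "\n".join(" ".join(repr(float(v)) for v in row) for row in arr)


def write_polydata(obj, path, point_scalars: dict | None = None) -> None:
    """Write a tree, mesh or point set as legacy ASCII VTK polydata."""
    path = Path(path)
    if str(path).lower().endswith((".ply", ".stl")):
        if not isinstance(obj, SurfaceMesh):
            raise ValueError("PLY/STL output is only supported for meshes")
        trimesh.Trimesh(obj.vertices, obj.faces, process=False).export(path)
        return
    lines = ["# vtk DataFile Version 3.0", "lusplan polydata", "ASCII",
             "DATASET POLYDATA"]
    scalars = dict(point_scalars or {})
    if isinstance(obj, VascularTree):
        pts = obj.points
        bifs = obj.bifurcations
        all_pts = np.vstack([pts, bifs]) if len(bifs) else pts
        lines.append(f"POINTS {len(all_pts)} float")
        lines.append(_fmt_floats(all_pts))
        n_cells = len(obj.branches)
        sizes = [len(b) for b in obj.branches]
        lines.append(f"LINES {n_cells} {n_cells + sum(sizes)}")
        off = 0
        for b in obj.branches:
            idx = range(off, off + len(b))
            lines.append(f"{len(b)} " + " ".join(str(i) for i in idx))
            off += len(b)
        if len(bifs):
            lines.append(f"VERTICES {len(bifs)} {2 * len(bifs)}")
            for i in range(len(bifs)):
                lines.append(f"1 {len(pts) + i}")
        n_data = len(all_pts)
    elif isinstance(obj, SurfaceMesh):
        lines.append(f"POINTS {len(obj.vertices)} float")
        lines.append(_fmt_floats(obj.vertices))
        f = obj.faces
        lines.append(f"POLYGONS {len(f)} {4 * len(f)}")
        for tri in f:
            lines.append("3 " + " ".join(str(int(i)) for i in tri))
        scalars.setdefault("visible", obj.visible_mask.astype(float))
        n_data = len(obj.vertices)
    else:
        pts = obj.points if isinstance(obj, PointSet) else np.asarray(obj, float)
        lines.append(f"POINTS {len(pts)} float")
        lines.append(_fmt_floats(pts))
        n_data = len(pts)
    if scalars:
        lines.append(f"POINT_DATA {n_data}")
        for name, vals in scalars.items():
            vals = np.asarray(vals, dtype=float).reshape(-1)
            if len(vals) != n_data:
                raise ValueError(f"scalar array {name!r} has wrong length")
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            lines.append("\n".join(repr(float(v)) for v in vals))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


class _Tok:
    """Whitespace tokenizer with parse-error context."""

    def __init__(self, text: str, path):
        self.toks = text.split()
        self.i = 0
        self.path = path

    def next(self, what: str) -> str:
        if self.i >= len(self.toks):
            raise ValueError(f"{self.path}: truncated file while reading {what}")
        t = self.toks[self.i]
        self.i += 1
        return t

    def next_int(self, what: str) -> int:
        t = self.next(what)
        try:
            return int(t)
        except ValueError:
            raise ValueError(f"{self.path}: expected integer for {what}, got {t!r}")

    def next_floats(self, n: int, what: str) -> np.ndarray:
        if self.i + n > len(self.toks):
            raise ValueError(f"{self.path}: truncated file while reading {what}")
        try:
            out = np.array(self.toks[self.i : self.i + n], dtype=float)
        except ValueError:
            raise ValueError(f"{self.path}: malformed number in {what}")
        self.i += n
        return out

    def peek(self) -> str | None:
        return self.toks[self.i] if self.i < len(self.toks) else None


def read_polydata(path):
    """Read legacy ASCII VTK polydata (or PLY/STL mesh).

    Returns a :class:`VascularTree` (LINES present), :class:`SurfaceMesh`
    (POLYGONS present) or :class:`PointSet` (no cells / VERTICES only).
    Named per-vertex scalar arrays are honoured: ``visible`` becomes the
    mesh visibility mask.  Mixed LINES+POLYGONS files are rejected.
    """
    path = Path(path)
    if str(path).lower().endswith((".ply", ".stl")):
        mesh = trimesh.load(path, force="mesh", process=False)
        return SurfaceMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    text = path.read_text(encoding="utf-8")
    header_end = 0
    for _ in range(4):  # version line, title, ASCII, DATASET
        header_end = text.find("\n", header_end) + 1
    head = text[:header_end]
    if "ASCII" not in head or "POLYDATA" not in head:
        raise ValueError(f"{path}: not an ASCII VTK polydata file")
    tok = _Tok(text[header_end:], path)

    points = None
    polylines: list[np.ndarray] = []
    triangles: list[list[int]] = []
    vertex_cells: list[int] = []
    scalars: dict[str, np.ndarray] = {}
    while tok.peek() is not None:
        kw = tok.next("keyword").upper()
        if kw == "POINTS":
            n = tok.next_int("point count")
            tok.next("point dtype")
            points = tok.next_floats(3 * n, "points").reshape(n, 3)
        elif kw in ("LINES", "POLYGONS", "VERTICES"):
            n_cells = tok.next_int(f"{kw} cell count")
            tok.next_int(f"{kw} size")
            for _ in range(n_cells):
                k = tok.next_int("cell length")
                idx = [tok.next_int("cell index") for _ in range(k)]
                if kw == "LINES":
                    polylines.append(np.asarray(idx, dtype=int))
                elif kw == "POLYGONS":
                    if k != 3:
                        raise ValueError(f"{path}: only triangle POLYGONS supported")
                    triangles.append(idx)
                else:
                    vertex_cells.extend(idx)
        elif kw == "POINT_DATA":
            tok.next_int("point data count")
        elif kw == "SCALARS":
            name = tok.next("scalar name")
            tok.next("scalar dtype")
            nxt = tok.peek()
            if nxt is not None and nxt.isdigit():
                tok.next_int("components")
            if (tok.peek() or "").upper() == "LOOKUP_TABLE":
                tok.next("lookup")
                tok.next("table name")
            if points is None:
                raise ValueError(f"{path}: SCALARS before POINTS")
            scalars[name] = tok.next_floats(len(points), f"scalars {name}")
        else:
            raise ValueError(f"{path}: unsupported element {kw!r}")
    if points is None:
        raise ValueError(f"{path}: file has no POINTS")
    if polylines and triangles:
        raise ValueError(f"{path}: mixed LINES and POLYGONS cells")
    if polylines:
        branches = [points[idx] for idx in polylines]
        bifs = points[vertex_cells] if vertex_cells else np.empty((0, 3))
        return VascularTree(branches, bifs)
    if triangles:
        visible = None
        if "visible" in scalars:
            visible = scalars["visible"] > 0.5
        mesh = SurfaceMesh(points, np.asarray(triangles, dtype=int), visible)
        mesh.scalars = {k: v for k, v in scalars.items() if k != "visible"}
        return mesh
    if vertex_cells:
        return PointSet(points[vertex_cells])
    ps = PointSet(points)
    ps.scalars = scalars
    return ps


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------


def write_landmarks_csv(points, path, labels=None) -> None:
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    df = pd.DataFrame(pts, columns=["x", "y", "z"])
    if labels is not None:
        df["label"] = list(labels)
    df.to_csv(path, index=False)


def read_landmarks_csv(path) -> PointSet:
    df = pd.read_csv(path)
    for c in ("x", "y", "z"):
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    labels = df["label"].astype(str).tolist() if "label" in df.columns else None
    return PointSet(df[["x", "y", "z"]].to_numpy(dtype=float), labels)


# ---------------------------------------------------------------------------
# tracked sweep container
# ---------------------------------------------------------------------------


def write_sweep_dir(sweep: TrackedSweep, outdir) -> None:
    out = Path(outdir)
    (out / "frames").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, frame in enumerate(sweep.frames):
        iio.imwrite(
            out / "frames" / f"{i:04d}.png",
            (frame.mask.astype(np.uint8) * 255),
        )
        rows.append([i] + [float(v) for v in frame.pose.as_matrix().ravel()])
    cols = ["frame"] + [f"m{r}{c}" for r in range(4) for c in range(4)]
    pd.DataFrame(rows, columns=cols).to_csv(out / "poses.csv", index=False)
    meta = {
        "pixel_spacing_mm": list(sweep.frames[0].pixel_spacing),
        "calibration": np.eye(4).tolist(),
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")
    write_landmarks_csv(sweep.digitised_surface, out / "digitised_surface.csv")
    write_landmarks_csv(sweep.landmarks_lus, out / "landmarks_lus.csv")
    write_landmarks_csv(sweep.landmarks_ct, out / "landmarks_ct.csv")


def read_sweep_dir(indir) -> TrackedSweep:
    ind = Path(indir)
    meta = json.loads((ind / "meta.json").read_text(encoding="utf-8"))
    spacing = tuple(float(v) for v in meta["pixel_spacing_mm"])
    calib = RigidTransform.from_matrix(np.asarray(meta["calibration"], dtype=float))
    poses = pd.read_csv(ind / "poses.csv")
    frames = []
    for _, row in poses.sort_values("frame").iterrows():
        i = int(row["frame"])
        mask = iio.imread(ind / "frames" / f"{i:04d}.png") > 127
        m = np.asarray(
            [row[f"m{r}{c}"] for r in range(4) for c in range(4)], dtype=float
        ).reshape(4, 4)
        pose = RigidTransform.from_matrix(m).compose(calib)
        frames.append(SweepFrame(mask, pose, spacing))
    return TrackedSweep(
        frames,
        read_landmarks_csv(ind / "digitised_surface.csv").points,
        read_landmarks_csv(ind / "landmarks_lus.csv").points,
        read_landmarks_csv(ind / "landmarks_ct.csv").points,
    )


# ---------------------------------------------------------------------------
# registration reports
# ---------------------------------------------------------------------------

REPORT_COLUMNS = [
    "dataset", "R_U_mm", "R_S_mm", "E_S_mm", "E_R_mm", "D_R_mm", "success",
]


def write_report(results: list[dict], path) -> None:
    """Write per-dataset registration results as JSON plus a CSV sibling.

    Each entry carries the uniqueness radius R_U, success radius R_S, the
    TRE at R_S (E_S), the reference-standard TRE (E_R), the distance D_R
    from the reference probe position to the R_U sample, a success flag and
    the full TRE curve.  Failed registrations store null R_S / E_S.
    Sentinel R_U (-1, not unique at the maximum radius) becomes null in
    JSON.
    """
    path = Path(path)

    def _clean(v):
        if v is None:
            return None
        v = float(v)
        if np.isnan(v) or v < 0:
            return None
        return v

    payload = []
    for r in results:
        entry = {
            "dataset": r["dataset"],
            "R_U_mm": _clean(r.get("R_U_mm")),
            "R_S_mm": _clean(r.get("R_S_mm")),
            "E_S_mm": _clean(r.get("E_S_mm")),
            "E_R_mm": _clean(r.get("E_R_mm")),
            "D_R_mm": _clean(r.get("D_R_mm")),
            "success": bool(r.get("success", False)),
        }
        curve = r.get("curve")
        if curve is not None:
            entry["curve"] = {
                "radii_mm": [float(x) for x in curve.radii],
                "rms_tre_mm": [
                    None if not np.isfinite(v) else float(v) for v in curve.rms_tre
                ],
            }
        payload.append(entry)
    path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
    rows = [{c: e.get(c) for c in REPORT_COLUMNS} for e in payload]
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(
        path.with_suffix(".csv"), index=False
    )


def read_report(path) -> list[dict]:
    return json.loads(Path(path).read_text(encoding="utf-8"))
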