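"""File formats: contour CSV/JSON, CC-representation JSON, pair corpora, SVG.

Coordinates are stored y-up (mathematical convention), object-centric with
the centroid near the origin; SVG export flips the y axis for display.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .contour import Contour, InvalidContourError, PX_PER_DEG
from .model import CCRepresentation, CCSegment, ModelParams
from .stimuli import ShapePair

__all__ = [
    "FormatError",
    "RunConfig",
    "load_run_config",
    "read_contour",
    "write_contour",
    "read_cc_json",
    "write_cc_json",
    "write_pairs_jsonl",
    "read_pairs_jsonl",
    "export_svg",
]

CC_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to the expected contour / representation format."""


@dataclass(frozen=True)
class RunConfig:
    """Run-level configuration: model parameters, sampling, seed, units.

    Defaults reproduce the standard parameterization (W = 0.04, T = 1.18,
    512-point sampling, 41.67 px/deg).
    """

    params: ModelParams = field(default_factory=ModelParams)
    seed: int = 0
    px_per_deg: float = PX_PER_DEG
    verbosity: int = 1


def load_run_config(path) -> RunConfig:
    """Load a RunConfig from YAML (with JSON fallback).

    Recognized keys: ``window_fraction``, ``merge_threshold``,
    ``merge_mode``, ``absolute_threshold``, ``n_points``, ``seed``,
    ``px_per_deg``, ``verbosity``.  Unknown keys raise a FormatError so
    typos do not silently fall back to defaults.
    """
    import yaml

    with open(path) as fh:
        text = fh.read()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError:
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: neither valid YAML nor JSON") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping")
    param_keys = {"window_fraction", "merge_threshold", "merge_mode",
                  "absolute_threshold", "zero_curvature_eps", "n_points",
                  "smoothing_halfwidth"}
    run_keys = {"seed", "px_per_deg", "verbosity"}
    unknown = set(data) - param_keys - run_keys
    if unknown:
        raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
    try:
        params = ModelParams(**{k: v for k, v in data.items()
                                if k in param_keys})
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: invalid model parameters ({exc})") from exc
    return RunConfig(params=params,
                     **{k: v for k, v in data.items() if k in run_keys})


def read_contour(path, closed: bool | None = None, unit: str = "pixel"
                 ) -> Contour:
    """Read a contour from CSV (columns x,y; header required) or JSON.

    JSON carries its own metadata (``{"unit": ..., "closed": ..., "points":
    [[x, y], ...]}``); for CSV the flags come from a sidecar JSON next to
    the file (``<name>.meta.json``) or from the keyword arguments.  A closed
    contour with a duplicated endpoint is deduplicated (implicit closure).
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        try:
            pts = np.asarray(data["points"], float)
            closed = bool(data["closed"])
            unit = data.get("unit", "pixel")
        except (KeyError, TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed contour JSON ({exc})") from exc
    else:
        sidecar = path.with_suffix(".meta.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                meta = json.load(fh)
            closed = bool(meta.get("closed", closed or False))
            unit = meta.get("unit", unit)
        rows = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is None or [h.strip().lower() for h in header[:2]] != ["x", "y"]:
                raise FormatError(f"{path}: missing x,y header row")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                try:
                    rows.append((float(row[0]), float(row[1])))
                except (ValueError, IndexError) as exc:
                    raise FormatError(
                        f"{path}: line {lineno}: cannot parse coordinates"
                    ) from exc
                if not np.isfinite(rows[-1]).all():
                    raise FormatError(f"{path}: line {lineno}: non-finite coordinate")
        pts = np.asarray(rows, float)
    if pts.ndim != 2 or pts.shape[0] < 8:
        raise FormatError(f"{path}: contour needs at least 8 points")
    try:
        return Contour(points=pts, closed=bool(closed), unit=unit)
    except InvalidContourError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_contour(contour: Contour, path) -> None:
    """Write a contour as CSV (x,y header) plus a metadata sidecar, or as a
    single self-describing JSON file if the path ends in .json."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"unit": contour.unit, "closed": contour.closed,
                       "points": contour.points.tolist()}, fh)
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        writer.writerows(contour.points.tolist())
    with open(path.with_suffix(".meta.json"), "w") as fh:
        json.dump({"unit": contour.unit, "closed": contour.closed}, fh)


def write_cc_json(rep: CCRepresentation, path) -> None:
    """Serialize a CC representation (schema-versioned JSON)."""
    data = {
        "schema_version": CC_SCHEMA_VERSION,
        "closed": rep.closed,
        "source_length": rep.source_length,
        "segments": [
            {"curvature": s.curvature, "arclength": s.arclength,
             "start": list(s.start_point),
             "tangent_deg": float(np.degrees(s.start_tangent))}
            for s in rep.segments
        ],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_cc_json(path) -> CCRepresentation:
    with open(path) as fh:
        data = json.load(fh)
    try:
        segs = tuple(
            CCSegment(curvature=float(s["curvature"]),
                      arclength=float(s["arclength"]),
                      start_point=tuple(s.get("start", (0.0, 0.0))),
                      start_tangent=float(np.radians(s.get("tangent_deg", 0.0))))
            for s in data["segments"]
        )
        if not segs:
            raise FormatError(f"{path}: representation has no segments")
        return CCRepresentation(segments=segs, closed=bool(data["closed"]),
                                source_length=float(data["source_length"]))
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"{path}: malformed CC JSON ({exc})") from exc


def write_pairs_jsonl(pairs, path) -> None:
    """Pair corpus as JSON-lines, one ShapePair per line with inline points."""
    with open(path, "w") as fh:
        for pair in pairs:
            fh.write(json.dumps({
                "seed": pair.seed,
                "similarity": pair.similarity,
                "segment_diff": pair.segment_diff,
                "shape_a": pair.shape_a.points.tolist(),
                "shape_b": pair.shape_b.points.tolist(),
            }) + "\n")


def read_pairs_jsonl(path) -> list[ShapePair]:
    pairs = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            pairs.append(ShapePair(
                shape_a=Contour(np.asarray(d["shape_a"]), closed=True),
                shape_b=Contour(np.asarray(d["shape_b"]), closed=True),
                similarity=d["similarity"],
                segment_diff=d.get("segment_diff"),
                seed=d.get("seed")))
    return pairs


def _svg_path(points, closed):
    cmds = [f"M {points[0][0]:.3f} {-points[0][1]:.3f}"]
    cmds += [f"L {x:.3f} {-y:.3f}" for x, y in points[1:]]
    if closed:
        cmds.append("Z")
    return " ".join(cmds)


def export_svg(items, path, stroke_width: float = 1.5) -> None:
    """Inspection SVG of contours and/or CC representations.

    Contours are drawn as black polylines; representations as one sub-path
    per segment, colored by curvature sign (blue counterclockwise, red
    clockwise, grey near-straight).  The y axis is flipped for display.
    """
    if isinstance(items, (Contour, CCRepresentation)):
        items = [items]
    from .model import reconstruct

    paths = []
    all_pts = []
    for item in items:
        if isinstance(item, Contour):
            pts = item.points
            paths.append((_svg_path(pts, item.closed), "black"))
            all_pts.append(pts)
        elif isinstance(item, CCRepresentation):
            rendered = reconstruct(item, points_per_segment=48,
                                   correct_closure=False)
            chunks = np.array_split(rendered.points, item.n_segments)
            for seg, chunk in zip(item.segments, chunks):
                eps = 1e-4 * 2 * np.pi / item.source_length
                color = ("grey" if abs(seg.curvature) < eps
                         else "blue" if seg.curvature > 0 else "red")
                paths.append((_svg_path(chunk, False), color))
                all_pts.append(chunk)
        else:
            raise TypeError(f"cannot export {type(item).__name__}")
    pts = np.vstack(all_pts)
    x0, y0 = pts.min(axis=0) - 10
    x1, y1 = pts.max(axis=0) + 10
    body = "\n".join(
        f'  <path d="{d}" fill="none" stroke="{color}" '
        f'stroke-width="{stroke_width}"/>'
        for d, color in paths)
    svg = (f'<svg xmlns="http://www.w3.org/2000/svg" '
           f'viewBox="{x0:.1f} {-y1:.1f} {x1 - x0:.1f} {y1 - y0:.1f}">\n'
           f"{body}\n</svg>\n")
    with open(path, "w") as fh:
        fh.write(svg)
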