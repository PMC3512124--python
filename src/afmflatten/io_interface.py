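"""Readers and writers for the supported height-map formats.

Three interchangeable formats, all storing heights in nanometers with
row 0 = first acquired scan line:

* plain-text numeric matrix, one scan line per row (precision ``%.9g``);
* raw 32-bit little-endian floats plus a JSON sidecar giving the
  dimensions, pixel size and units (exact round trip at float32);
* single-channel float TIFF (via tifffile).

Every writer emits a JSON sidecar ``<payload>.json`` carrying the image
metadata and, when present, the synthetic ground-truth distortion record.
Sequences are written as one payload per frame plus an ordered manifest.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

from .image import HeightImage, ImageParseError
from .surface_ops import PolynomialSurface
from .synthetic_afm import DistortionRecord

_TEXT_SUFFIXES = {".txt", ".asc", ".dat", ".tsv", ".xyz"}
_RAW_SUFFIXES = {".raw", ".bin"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    s = path.suffix.lower()
    if s in _TEXT_SUFFIXES:
        return "txt"
    if s in _RAW_SUFFIXES:
        return "raw"
    if s in _TIFF_SUFFIXES:
        return "tiff"
    raise ImageParseError(f"cannot infer format from suffix {s!r} of {path}")


def _read_text_matrix(path: Path) -> np.ndarray:
    rows: List[List[float]] = []
    width = None
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise ImageParseError(
                    f"{path}: non-numeric cell on line {lineno}: {exc}"
                ) from None
            if width is None:
                width = len(values)
            elif len(values) != width:
                raise ImageParseError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(values)} cells, expected {width})"
                )
            rows.append(values)
    if not rows:
        raise ImageParseError(f"{path}: no numeric data found")
    return np.asarray(rows, dtype=float)


def _load_sidecar(path: Path) -> dict:
    sc = _sidecar_path(path)
    if sc.exists():
        with open(sc) as fh:
            return json.load(fh)
    return {}


def read_image(path, fmt: Optional[str] = None) -> HeightImage:
    """Read a height map; heights in nm, row 0 = first acquired line.

    Format is auto-detected from the suffix unless ``fmt`` ("txt", "raw",
    "tiff") is given.  The raw format requires its JSON sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, fmt)
    meta = _load_sidecar(path)
    if fmt == "txt":
        heights = _read_text_matrix(path)
    elif fmt == "raw":
        if not meta:
            raise ImageParseError(f"{path}: raw format requires sidecar {_sidecar_path(path)}")
        rows, cols = int(meta["rows"]), int(meta["cols"])
        payload = np.fromfile(path, dtype="<f4")
        if payload.size != rows * cols:
            raise ImageParseError(
                f"{path}: payload holds {payload.size} values but sidecar "
                f"declares {rows}x{cols}={rows * cols}"
            )
        heights = payload.astype(float).reshape(rows, cols)
    elif fmt == "tiff":
        import tifffile

        heights = np.asarray(tifffile.imread(path), dtype=float)
        if heights.ndim != 2:
            raise ImageParseError(f"{path}: expected a single-channel 2-D TIFF")
    else:
        raise ImageParseError(f"unknown format {fmt!r}")
    if meta.get("rows") is not None and fmt != "raw":
        if (int(meta["rows"]), int(meta["cols"])) != heights.shape:
            raise ImageParseError(
                f"{path}: sidecar dimensions {meta['rows']}x{meta['cols']} "
                f"do not match payload shape {heights.shape}"
            )
    metadata = {}
    if meta.get("ground_truth") is not None:
        metadata["ground_truth"] = DistortionRecord.from_dict(meta["ground_truth"])
    return HeightImage(
        heights,
        pixel_size=float(meta.get("pixel_size", 1.0)),
        channel=meta.get("channel", "height"),
        frame_index=meta.get("frame_index"),
        metadata=metadata,
    )


def write_image(
    image: HeightImage,
    path,
    fmt: Optional[str] = None,
    ground_truth: Optional[DistortionRecord] = None,
) -> None:
    """Write a height map and its JSON sidecar.

    ``ground_truth`` (or an existing record in ``image.metadata``) is
    serialised into the sidecar so synthetic data stays self-describing.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "txt":
        np.savetxt(path, image.heights, fmt="%.9g")
    elif fmt == "raw":
        image.heights.astype("<f4").tofile(path)
    elif fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, image.heights.astype(np.float32))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    record = ground_truth or image.metadata.get("ground_truth")
    sidecar = {
        "rows": image.rows,
        "cols": image.cols,
        "pixel_size": image.pixel_size,
        "units": "nm",
        "channel": image.channel,
        "frame_index": image.frame_index,
        "format": fmt,
        "dtype": "<f4" if fmt == "raw" else None,
        "ground_truth": record.to_dict() if record is not None else None,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def write_sequence(
    frames: Sequence[HeightImage],
    directory,
    prefix: str = "frame",
    fmt: str = "raw",
) -> Path:
    """Write N frames plus an ordered manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    suffix = {"txt": ".txt", "raw": ".raw", "tiff": ".tif"}[fmt]
    names = []
    for i, frame in enumerate(frames):
        name = f"{prefix}_{i:04d}{suffix}"
        frame = frame.copy()
        frame.frame_index = i
        write_image(frame, directory / name, fmt=fmt)
        names.append(name)
    manifest = directory / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"frames": names, "format": fmt}, fh, indent=1)
    return manifest


def read_sequence(manifest_path) -> List[HeightImage]:
    """Read frames back in the order the manifest lists them."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = manifest_path.parent
    return [
        read_image(base / name, fmt=manifest.get("format")) for name in manifest["frames"]
    ]


def discover_inputs(target) -> List[Path]:
    """Batch discovery: a directory (all supported files, sorted), a glob
    pattern, or a single file."""
    target = str(target)
    p = Path(target)
    supported = _TEXT_SUFFIXES | _RAW_SUFFIXES | _TIFF_SUFFIXES
    if p.is_dir():
        manifest = p / "manifest.json"
        if manifest.exists():
            with open(manifest) as fh:
                names = json.load(fh)["frames"]
            return [p / n for n in names]
        return sorted(q for q in p.iterdir() if q.suffix.lower() in supported)
    if any(ch in target for ch in "*?["):
        parent = Path(target).parent
        return sorted(parent.glob(Path(target).name))
    return [p]


def write_step_log(step_log, path) -> None:
    """Serialise a pipeline step log as structured text (JSON)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump([rec.to_dict() for rec in step_log], fh, indent=1)


def write_surface(surface: PolynomialSurface, path) -> None:
    """Serialise a fitted background surface (order + coefficients)."""
    with open(Path(path), "w") as fh:
        json.dump(surface.to_dict(), fh, indent=1)


def read_surface(path) -> PolynomialSurface:
    with open(Path(path)) as fh:
        return PolynomialSurface.from_dict(json.load(fh))
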