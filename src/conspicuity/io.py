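"""Reading and writing images, maps, fixation tables and dataset layouts.

The standard dataset layout is a directory containing ``images/`` (PNG or
JPEG scenes) and ``fixations.csv`` with header
``image_id,subject_id,x,y,order`` (``order`` optional).  Conspicuity maps
round-trip losslessly at 16-bit precision as grayscale PNGs with a sidecar
JSON recording the scale factor, or as plain-text matrices.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .density import FixationRecord
from .errors import DataValidationError
from .features import FeatureMap, RasterImage

__all__ = [
    "load_image",
    "save_image",
    "save_map",
    "load_map",
    "read_fixation_table",
    "write_fixation_table",
    "load_dataset",
    "import_dataset",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("image_id", "subject_id", "x", "y")


def load_image(path: str | Path, image_id: str | None = None) -> RasterImage:
    """Read an 8-bit RGB PNG/JPEG into a [0, 1] float image."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=float) / 255.0
    return RasterImage(arr, image_id=image_id or path.stem)


def save_image(image: RasterImage, path: str | Path) -> Path:
    path = Path(path)
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)
    return path


def save_map(fmap: FeatureMap, path: str | Path, fmt: str = "png16") -> Path:
    """Write a map as 16-bit grayscale PNG (+ sidecar JSON) or text matrix."""
    path = Path(path)
    if fmt == "png16":
        peak = float(fmap.values.max())
        scale = peak / 65535.0 if peak > 0 else 1.0
        quant = np.round(fmap.values / scale if peak > 0 else fmap.values)
        Image.fromarray(quant.astype(np.uint16)).save(path)
        sidecar = {
            "scale": scale,
            "map_kind": fmap.map_kind,
            "source_image_id": fmap.source_image_id,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, sort_keys=True)
        )
    elif fmt == "txt":
        header = json.dumps(
            {"map_kind": fmap.map_kind, "source_image_id": fmap.source_image_id}
        )
        np.savetxt(path, fmap.values, header=header)
    else:
        raise ValueError(f"unknown map format {fmt!r}")
    return path


def load_map(path: str | Path, fmt: str = "png16") -> FeatureMap:
    path = Path(path)
    if fmt == "png16":
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        with Image.open(path) as im:
            quant = np.asarray(im, dtype=float)
        return FeatureMap(
            sidecar["map_kind"],
            quant * sidecar["scale"],
            sidecar["source_image_id"],
        )
    if fmt == "txt":
        with open(path) as fh:
            meta = json.loads(fh.readline().lstrip("# ").strip())
        values = np.loadtxt(path)
        return FeatureMap(meta["map_kind"], values, meta["source_image_id"])
    raise ValueError(f"unknown map format {fmt!r}")


def read_fixation_table(path: str | Path) -> list[FixationRecord]:
    """Parse the standard fixation CSV into validated records.

    Rows with non-numeric or negative coordinates are rejected and logged
    with their (1-based, header-inclusive) line numbers; a missing ``order``
    column is allowed and leaves the saccade index unset.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path} is missing required columns: {', '.join(missing)}"
        )
    has_order = "order" in df.columns
    records: list[FixationRecord] = []
    rejected: list[int] = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # 1-based, after the header line
        try:
            x, y = float(row.x), float(row.y)
            if not (np.isfinite(x) and np.isfinite(y)) or x < 0 or y < 0:
                raise ValueError
            order = None
            if has_order and isinstance(row.order, str) and row.order.strip():
                order = int(float(row.order))
        except (TypeError, ValueError):
            rejected.append(line_no)
            continue
        records.append(
            FixationRecord(
                image_id=str(row.image_id),
                subject_id=str(row.subject_id),
                x=x,
                y=y,
                order=order,
            )
        )
    if rejected:
        log.warning(
            "%s: rejected %d malformed row(s) at line(s) %s",
            path,
            len(rejected),
            ", ".join(map(str, rejected)),
        )
    return records


def write_fixation_table(
    records: Iterable[FixationRecord], path: str | Path
) -> Path:
    path = Path(path)
    rows = [
        {
            "image_id": r.image_id,
            "subject_id": r.subject_id,
            "x": r.x,
            "y": r.y,
            "order": "" if r.order is None else r.order,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["image_id", "subject_id", "x", "y", "order"]).to_csv(
        path, index=False
    )
    return path


IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def load_dataset(
    dataset_dir: str | Path,
) -> list[tuple[str, RasterImage, list[FixationRecord]]]:
    """Read a standard-layout dataset directory.

    Returns (image_id, image, fixation records) triples sorted by image id;
    images without any fixation records are returned with an empty list so
    the caller can decide how to log the exclusion.
    """
    root = Path(dataset_dir)
    images_dir = root / "images"
    fix_path = root / "fixations.csv"
    if not images_dir.is_dir():
        raise DataValidationError(f"{images_dir} does not exist")
    if not fix_path.is_file():
        raise DataValidationError(f"{fix_path} does not exist")
    records = read_fixation_table(fix_path)
    by_image: dict[str, list[FixationRecord]] = {}
    for r in records:
        by_image.setdefault(r.image_id, []).append(r)
    out = []
    for img_path in sorted(images_dir.iterdir()):
        if img_path.suffix.lower() not in IMAGE_SUFFIXES:
            continue
        image_id = img_path.stem
        out.append((image_id, load_image(img_path), by_image.get(image_id, [])))
    if not out:
        raise DataValidationError(f"no images found under {images_dir}")
    return out


def import_dataset(
    source_dir: str | Path,
    out_dir: str | Path,
    layout: str = "generic",
) -> Path:
    """Convert a public eye-tracking dataset folder to the standard layout.

    Import only -- nothing is downloaded.  Supported layouts:

    * ``generic``: already ``images/`` + ``fixations.csv``; files are copied.
    * ``per-image-csv`` (Toronto/MIT/Ehinger/NUSEF-style exports): a folder
      of images plus one ``<image>_fixations.csv`` per image with columns
      ``subject_id,x,y[,order]``; rows are merged into one table.
    """
    source, out = Path(source_dir), Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    if layout == "generic":
        for img in sorted((source / "images").iterdir()):
            if img.suffix.lower() in IMAGE_SUFFIXES:
                (out / "images" / img.name).write_bytes(img.read_bytes())
        (out / "fixations.csv").write_bytes((source / "fixations.csv").read_bytes())
        return out
    if layout == "per-image-csv":
        merged: list[FixationRecord] = []
        for img in sorted(source.iterdir()):
            if img.suffix.lower() not in IMAGE_SUFFIXES:
                continue
            (out / "images" / img.name).write_bytes(img.read_bytes())
            table = img.with_name(f"{img.stem}_fixations.csv")
            if not table.is_file():
                log.warning("no fixation table for %s", img.name)
                continue
            df = pd.read_csv(table)
            for row in df.itertuples(index=False):
                merged.append(
                    FixationRecord(
                        image_id=img.stem,
                        subject_id=str(row.subject_id),
                        x=float(row.x),
                        y=float(row.y),
                        order=int(row.order) if hasattr(row, "order") else None,
                    )
                )
        write_fixation_table(merged, out / "fixations.csv")
        return out
    raise ValueError(f"unknown dataset layout {layout!r}")
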