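"""Reading and writing bounding-box annotations.

Two on-disk formats are supported:

* the package's CSV dialect — header
  ``image,structure,x_min,y_min,x_max,y_max`` with ``structure`` one of
  ``OD`` (optic disc) or ``OC`` (optic cup), one row per structure per
  image;
* COCO-style JSON, where each annotation carries ``bbox`` as
  ``[x, y, width, height]`` and a ``category_id`` mapped to OD/OC through
  the file's ``categories`` list.  Boxes are converted to corner form on
  load.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .geometry import BoundingBox

__all__ = [
    "STRUCTURES",
    "read_annotations_csv",
    "write_annotations_csv",
    "read_annotations_coco",
]

STRUCTURES = ("OD", "OC")
_CSV_COLUMNS = ["image", "structure", "x_min", "y_min", "x_max", "y_max"]

#: image id -> {"OD": BoundingBox, "OC": BoundingBox}
AnnotationMap = dict[str, dict[str, BoundingBox]]


def read_annotations_csv(path: str | Path) -> AnnotationMap:
    """Read the CSV dialect into ``{image: {structure: box}}``."""
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV {path} missing columns: {sorted(missing)}")
    out: AnnotationMap = {}
    for row in df.itertuples(index=False):
        structure = str(row.structure)
        if structure not in STRUCTURES:
            raise ValueError(f"unknown structure {structure!r} in {path}")
        box = BoundingBox(float(row.x_min), float(row.y_min), float(row.x_max), float(row.y_max))
        out.setdefault(str(row.image), {})[structure] = box
    return out


def write_annotations_csv(annotations: AnnotationMap, path: str | Path) -> None:
    """Write ``{image: {structure: box}}`` in the CSV dialect.

    Rows are emitted sorted by image id then structure (OD before OC) so
    repeated writes of the same mapping are byte-identical.
    """
    rows = []
    for image in sorted(annotations):
        for structure in STRUCTURES:
            if structure in annotations[image]:
                box = annotations[image][structure]
                rows.append((image, structure, box.x_min, box.y_min, box.x_max, box.y_max))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_annotations_coco(path: str | Path) -> AnnotationMap:
    """Read COCO-style JSON; category names must be OD/OC (case-insensitive)."""
    with open(path) as fh:
        doc = json.load(fh)
    images = {img["id"]: str(img.get("file_name", img["id"])) for img in doc["images"]}
    categories = {}
    for cat in doc["categories"]:
        name = str(cat["name"]).upper()
        if name not in STRUCTURES:
            raise ValueError(f"unknown category {cat['name']!r} in {path}")
        categories[cat["id"]] = name
    out: AnnotationMap = {}
    for ann in doc["annotations"]:
        x, y, w, h = (float(v) for v in ann["bbox"])
        box = BoundingBox.from_xywh(x, y, w, h)
        out.setdefault(images[ann["image_id"]], {})[categories[ann["category_id"]]] = box
    return out
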