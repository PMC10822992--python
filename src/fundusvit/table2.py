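"""Packaged reference fixture of nine annotated test images.

The fixture reproduces, verbatim, a published table of ground-truth and
predicted optic-disc (OD) and optic-cup (OC) bounding boxes with their
radii, OC/OD ratios, and binary classifications for nine fundus images.
It serves two purposes: an exact-reproduction oracle for the geometry
module, and a worked example of the screening arithmetic.

The printed table is internally inconsistent in places, and the loader
flags this rather than silently repairing it:

* the GT OC box column for rows 1-8 duplicates the GT OD column shifted
  up by one row (``oc_box_duplicated``);
* the printed GT ratios are reproducible from the printed boxes only for
  images 1 and 2 (``gt_ratio_consistent``);
* the printed predicted radii carry decimals reproducible from the printed
  integer predicted boxes only for image 2 (``pred_od_radius_consistent``),
  presumably because they were computed from unrounded float predictions.

All values are retained exactly as printed; consistency flags are derived
at load time.  Records with ``self_consistent=False`` are excluded from
exact-reproduction tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .geometry import BoundingBox, RadiusConvention, diagnose, radius, GLAUCOMA

__all__ = ["Table2Record", "Table2Fixture", "load_table2_fixture"]

_BOX_PREFIXES = ("gt_od", "pred_od", "gt_oc", "pred_oc")


@dataclass(frozen=True)
class Table2Record:
    """One image row of the reference table, plus derived consistency flags."""

    image: int
    gt_od_box: BoundingBox
    pred_od_box: BoundingBox
    gt_oc_box: BoundingBox
    pred_oc_box: BoundingBox
    gt_od_radius: float
    pred_od_radius: float
    gt_oc_radius: float
    pred_oc_radius: float
    gt_ratio: float
    pred_ratio: float
    actual_class: int
    predicted_class: int
    # derived flags
    gt_od_radius_consistent: bool
    pred_od_radius_consistent: bool
    gt_oc_radius_consistent: bool
    pred_oc_radius_consistent: bool
    oc_box_duplicated: bool
    gt_ratio_consistent: bool
    pred_ratio_consistent: bool
    classes_consistent: bool
    self_consistent: bool


@dataclass(frozen=True)
class Table2Fixture:
    """All nine records plus convenience accessors."""

    records: tuple[Table2Record, ...]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, image: int) -> Table2Record:
        """Look up a record by its 1-based image id."""
        for rec in self.records:
            if rec.image == image:
                return rec
        raise KeyError(f"no record for image {image}")

    @property
    def actual_classes(self) -> list[int]:
        return [r.actual_class for r in self.records]

    @property
    def predicted_classes(self) -> list[int]:
        return [r.predicted_class for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict = {"image": r.image}
            for prefix in _BOX_PREFIXES:
                box: BoundingBox = getattr(r, f"{prefix}_box")
                row[f"{prefix}_box"] = box.as_tuple()
            for field in (
                "gt_od_radius", "pred_od_radius", "gt_oc_radius", "pred_oc_radius",
                "gt_ratio", "pred_ratio", "actual_class", "predicted_class",
                "self_consistent",
            ):
                row[field] = getattr(r, field)
            rows.append(row)
        return pd.DataFrame(rows)


def _read_raw() -> pd.DataFrame:
    with resources.files("fundusvit.data").joinpath("table2.csv").open("r") as fh:
        return pd.read_csv(fh)


def _round1_eq(computed: float, printed: float) -> bool:
    return round(computed, 1) == round(printed, 1)


def load_table2_fixture() -> Table2Fixture:
    """Load the packaged reference table and derive consistency flags."""
    raw = _read_raw()
    semi = RadiusConvention.SEMI_MAJOR
    records: list[Table2Record] = []
    n = len(raw)
    for i, row in raw.iterrows():
        boxes = {
            prefix: BoundingBox(
                row[f"{prefix}_x_min"], row[f"{prefix}_y_min"],
                row[f"{prefix}_x_max"], row[f"{prefix}_y_max"],
            )
            for prefix in _BOX_PREFIXES
        }
        # OC box corruption: row i's GT OC box repeats row i+1's GT OD box
        duplicated = False
        if i + 1 < n:
            nxt = raw.iloc[i + 1]
            duplicated = all(
                row[f"gt_oc_{c}"] == nxt[f"gt_od_{c}"]
                for c in ("x_min", "y_min", "x_max", "y_max")
            )
        gt_ratio_comp = radius(boxes["gt_oc"], semi) / radius(boxes["gt_od"], semi)
        pred_ratio_comp = (
            radius(boxes["pred_oc"], semi) / radius(boxes["pred_od"], semi)
        )
        flags = dict(
            gt_od_radius_consistent=_round1_eq(radius(boxes["gt_od"], semi), row.gt_od_radius),
            pred_od_radius_consistent=_round1_eq(radius(boxes["pred_od"], semi), row.pred_od_radius),
            gt_oc_radius_consistent=_round1_eq(radius(boxes["gt_oc"], semi), row.gt_oc_radius),
            pred_oc_radius_consistent=_round1_eq(radius(boxes["pred_oc"], semi), row.pred_oc_radius),
            oc_box_duplicated=duplicated,
            gt_ratio_consistent=_round1_eq(gt_ratio_comp, row.gt_ratio),
            pred_ratio_consistent=_round1_eq(pred_ratio_comp, row.pred_ratio),
            classes_consistent=(
                (diagnose(row.gt_ratio) == GLAUCOMA) == bool(row.actual_class)
                and (diagnose(row.pred_ratio) == GLAUCOMA) == bool(row.predicted_class)
            ),
        )
        flags["self_consistent"] = bool(
            flags["gt_ratio_consistent"] and flags["classes_consistent"]
        )
        records.append(
            Table2Record(
                image=int(row.image),
                gt_od_box=boxes["gt_od"],
                pred_od_box=boxes["pred_od"],
                gt_oc_box=boxes["gt_oc"],
                pred_oc_box=boxes["pred_oc"],
                gt_od_radius=float(row.gt_od_radius),
                pred_od_radius=float(row.pred_od_radius),
                gt_oc_radius=float(row.gt_oc_radius),
                pred_oc_radius=float(row.pred_oc_radius),
                gt_ratio=float(row.gt_ratio),
                pred_ratio=float(row.pred_ratio),
                actual_class=int(row.actual_class),
                predicted_class=int(row.predicted_class),
                **flags,
            )
        )
    return Table2Fixture(records=tuple(records))
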