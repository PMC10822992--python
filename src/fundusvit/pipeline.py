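"""End-to-end screening: detect disc and cup, compute CDR, diagnose, evaluate.

One screening run takes a set of fundus images plus a trained disc model
and cup model, and produces per-image records — predicted OD/OC boxes, the
cup-to-disc ratio, the binary diagnosis, and the auxiliary rim width — and,
when ground truth is supplied, an evaluation report (confusion metrics from
the diagnoses, mean IoU of the predicted boxes, ROC/PR from the continuous
ratio).

Per-sample failures (unreadable image, failed CDR) are isolated: they are
recorded on the sample and the run continues.  Structural errors — models
whose configurations disagree — abort the run.  Given fixed models, inputs
and configuration the output is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .annotations import AnnotationMap
from .detector import ViTDetector, preprocess
from .evaluation import EvalReport, confusion_metrics, iou, pr_curve, roc_curve
from .geometry import (
    BoundingBox, CdrResult, DEFAULT_THRESHOLD, GLAUCOMA, RadiusConvention,
    compute_cdr, diagnose, radius,
)
from .table2 import load_table2_fixture

__all__ = ["ScreeningRecord", "run_screening", "screening_to_csv", "table2_check"]


@dataclass(frozen=True)
class ScreeningRecord:
    """Outcome of the pipeline for one image.

    ``rim_width`` (disc radius minus cup radius under the active
    convention) is an auxiliary proxy for neuroretinal-rim thickness; the
    diagnosis itself rests solely on the CDR rule.  ``error`` is set, and
    the other fields are ``None``, when the sample failed.
    """

    sample_id: str
    od_box: BoundingBox | None
    oc_box: BoundingBox | None
    cdr: CdrResult | None
    error: str | None = None

    @property
    def rim_width(self) -> float | None:
        return None if self.cdr is None else self.cdr.rim_width


def _load_image(item) -> tuple[str, np.ndarray]:
    if isinstance(item, (str, Path)):
        path = Path(item)
        img = iio.imread(path)
        if img.ndim == 3 and img.shape[2] == 4:  # drop alpha
            img = img[..., :3]
        return path.name, img
    sample_id, img = item
    return str(sample_id), np.asarray(img)


def _scale_box(box: BoundingBox, sx: float, sy: float) -> BoundingBox:
    return BoundingBox(box.x_min * sx, box.y_min * sy, box.x_max * sx, box.y_max * sy)


def run_screening(
    images: Sequence,
    od_model: ViTDetector | None,
    oc_model: ViTDetector | None,
    *,
    convention: RadiusConvention | str = RadiusConvention.SEMI_MAJOR,
    threshold: float = DEFAULT_THRESHOLD,
    ground_truth: AnnotationMap | None = None,
    labels: dict[str, int] | None = None,
    use_ground_truth_boxes: bool = False,
) -> tuple[list[ScreeningRecord], EvalReport | None]:
    """Screen a set of images; evaluate when ground truth is available.

    ``images`` is a sequence of file paths or ``(sample_id, array)`` pairs.
    With ``use_ground_truth_boxes=True`` the models are bypassed and the
    annotated boxes in ``ground_truth`` are replayed through the geometry
    stage (an oracle-detector run; useful for isolating the diagnosis
    rule).  Otherwise each image is preprocessed to the models' input size
    and both boxes are predicted in that frame.

    Returns the per-image records and, when ``labels`` (sample_id -> 0/1)
    are supplied, an :class:`EvalReport` with confusion metrics, ROC/PR on
    the continuous ratio, and — when ``ground_truth`` boxes are present and
    models were used — the mean IoU over predicted boxes.
    """
    if not use_ground_truth_boxes:
        if od_model is None or oc_model is None:
            raise ValueError("both models are required unless use_ground_truth_boxes")
        if od_model.config != oc_model.config:
            raise ValueError(
                "OD and OC model configurations differ; refusing to run: "
                f"{od_model.config} vs {oc_model.config}"
            )
    elif ground_truth is None:
        raise ValueError("use_ground_truth_boxes requires ground_truth annotations")

    records: list[ScreeningRecord] = []
    ious: list[float] = []
    for item in images:
        try:
            sample_id, img = _load_image(item)
        except (OSError, ValueError) as exc:
            sid = Path(item).name if isinstance(item, (str, Path)) else str(item[0])
            records.append(ScreeningRecord(sid, None, None, None, error=str(exc)))
            continue
        try:
            if use_ground_truth_boxes:
                ann = ground_truth[sample_id]
                od_box, oc_box = ann["OD"], ann["OC"]
            else:
                size = od_model.config.image_size
                pre = preprocess(img, size)
                od_box = od_model.predict_box(pre)
                oc_box = oc_model.predict_box(pre)
                if ground_truth is not None and sample_id in ground_truth:
                    h, w = img.shape[:2]
                    gt = ground_truth[sample_id]
                    gt_od = _scale_box(gt["OD"], size / w, size / h)
                    gt_oc = _scale_box(gt["OC"], size / w, size / h)
                    ious.append((iou(od_box, gt_od) + iou(oc_box, gt_oc)) / 2.0)
            cdr = compute_cdr(oc_box, od_box, convention, threshold)
            records.append(ScreeningRecord(sample_id, od_box, oc_box, cdr))
        except (KeyError, ValueError) as exc:
            records.append(ScreeningRecord(sample_id, None, None, None, error=str(exc)))

    report = None
    if labels is not None:
        ok = [r for r in records if r.error is None and r.sample_id in labels]
        actual = [labels[r.sample_id] for r in ok]
        predicted = [1 if r.cdr.diagnosis == GLAUCOMA else 0 for r in ok]
        scores = [r.cdr.ratio for r in ok]
        if ok:
            report = confusion_metrics(actual, predicted)
            try:
                report.roc_points, report.auc = roc_curve(scores, actual)
                report.pr_points, report.average_precision = pr_curve(scores, actual)
            except ValueError:
                pass  # single-class truth: curves stay None
        else:
            report = EvalReport()
        if ious:
            report.mean_iou = float(np.mean(ious))
    return records, report


_CSV_HEADER = (
    "sample_id,od_x_min,od_y_min,od_x_max,od_y_max,"
    "oc_x_min,oc_y_min,oc_x_max,oc_y_max,ratio,diagnosis,rim_width,error"
)


def screening_to_csv(records: Sequence[ScreeningRecord], path: str | Path) -> None:
    """Write screening records as CSV; byte-identical for identical inputs."""
    lines = [_CSV_HEADER]
    for r in records:
        if r.error is not None:
            lines.append(f"{r.sample_id},,,,,,,,,,,,{r.error!r}")
            continue
        ob, cb = r.od_box, r.oc_box
        lines.append(
            f"{r.sample_id},{ob.x_min:.4f},{ob.y_min:.4f},{ob.x_max:.4f},{ob.y_max:.4f},"
            f"{cb.x_min:.4f},{cb.y_min:.4f},{cb.x_max:.4f},{cb.y_max:.4f},"
            f"{r.cdr.ratio:.6f},{r.cdr.diagnosis},{r.rim_width:.4f},"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def table2_check(convention: RadiusConvention | str = RadiusConvention.SEMI_MAJOR) -> dict:
    """Recompute the packaged reference table and compare to printed values.

    Checks, under the given radius convention: every GT disc radius against
    its printed value; GT cup radii against the printed cup radii; the one
    predicted disc radius that is reproducible from its printed box; the
    printed GT ratios against box-derived ratios (only the self-consistent
    rows are expected to match); and both classification columns
    recomputed from the printed ratios with the inclusive 0.6 rule.

    Returns a report dict with per-check counts, a ``passed`` flag for the
    expectations that should hold, and a list of per-row discrepancies for
    the rows flagged inconsistent.
    """
    fixture = load_table2_fixture()
    conv = RadiusConvention(convention)
    gt_od_matches, gt_oc_matches, pred_od_matches = [], [], []
    ratio_matches, discrepancies = [], []
    actual_ok, predicted_ok = [], []
    for rec in fixture:
        r_od = radius(rec.gt_od_box, conv)
        r_oc = radius(rec.gt_oc_box, conv)
        gt_od_matches.append(round(r_od, 1) == rec.gt_od_radius)
        gt_oc_matches.append(round(r_oc, 1) == rec.gt_oc_radius)
        pred_od_matches.append(
            round(radius(rec.pred_od_box, conv), 1) == rec.pred_od_radius
        )
        ratio_ok = round(r_oc / r_od, 1) == rec.gt_ratio
        ratio_matches.append(ratio_ok)
        if not ratio_ok:
            discrepancies.append(
                {
                    "image": rec.image,
                    "printed_gt_ratio": rec.gt_ratio,
                    "recomputed_gt_ratio": round(r_oc / r_od, 3),
                    "oc_box_duplicated": rec.oc_box_duplicated,
                }
            )
        actual_ok.append(
            (diagnose(rec.gt_ratio) == GLAUCOMA) == bool(rec.actual_class)
        )
        predicted_ok.append(
            (diagnose(rec.pred_ratio) == GLAUCOMA) == bool(rec.predicted_class)
        )
    n = len(fixture)
    report = {
        "convention": conv.value,
        "n_records": n,
        "gt_od_radius_matches": int(sum(gt_od_matches)),
        "gt_oc_radius_matches": int(sum(gt_oc_matches)),
        "pred_od_radius_matches": int(sum(pred_od_matches)),
        "gt_ratio_matches": int(sum(ratio_matches)),
        "actual_class_matches": int(sum(actual_ok)),
        "predicted_class_matches": int(sum(predicted_ok)),
        "self_consistent_images": [r.image for r in fixture if r.self_consistent],
        "discrepancies": discrepancies,
    }
    # under the default convention all radii and both class columns must match
    report["passed"] = bool(
        conv is not RadiusConvention.SEMI_MAJOR
        or (
            sum(gt_od_matches) == n
            and sum(gt_oc_matches) == n
            and all(actual_ok)
            and all(predicted_ok)
        )
    )
    return report
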