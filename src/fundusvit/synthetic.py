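"""Synthetic fundus-like images with known optic-disc/cup annotations.

Real fundus photographs show a reddish-orange retina, a bright elliptical
optic disc, a still-brighter central cup, and dark branching vessels.  The
generator emulates exactly those features — a radial background gradient
with Gaussian noise, an axis-aligned elliptical disc, a concentric (or
vertically offset) cup whose semi-axes are the disc's scaled by the true
cup-to-disc ratio, and dark quadratic vessel curves radiating through the
disc — so that detector training, CDR screening and evaluation are fully
testable without any photograph download.

Ground truth is exact by construction: the OD and OC bounding boxes are the
analytic (continuous, sub-pixel) tight axis-aligned bounds of the rendered
ellipses — so the semi-major box radius equals the ellipse semi-major axis
and the box-derived cup-to-disc ratio equals the sampled CDR identically,
with the rasterized pixel mask agreeing to within half a pixel — the true
CDR is the sampled ratio, and the binary label applies the standard
inclusive 0.6 rule to it.  Ellipses (not circles) are used deliberately so the euclidean,
semi-major and vertical radius conventions genuinely differ on synthetic
data.

All randomness flows through one explicitly seeded ``numpy`` generator;
there is no global random state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import bezier_curve, ellipse

from .annotations import write_annotations_csv
from .geometry import BoundingBox, DEFAULT_THRESHOLD

__all__ = ["SyntheticConfig", "FundusSample", "generate_sample", "generate_dataset"]

# rendering palette (RGB in [0, 1]); loosely matched to fundus photography
_BG_COLOR = np.array([0.62, 0.28, 0.12])
_DISC_COLOR = np.array([0.93, 0.72, 0.42])
_CUP_COLOR = np.array([1.00, 0.92, 0.60])
_VESSEL_COLOR = np.array([0.40, 0.10, 0.06])


@dataclass(frozen=True)
class SyntheticConfig:
    """Rendering and sampling parameters for one synthetic dataset.

    Parameters
    ----------
    image_size
        Side length in pixels of the square output image.
    od_radius_range
        Interval (min, max) for the disc's semi-major axis in pixels; must
        fit inside the image with a small margin.  ``None`` (default)
        scales with the image: 25-50 px at 224, i.e. roughly a disc
        diameter of a quarter to a half of the frame, as in typical
        disc-centred fundus crops.
    cdr_range
        Interval for the uniform law of the true cup-to-disc ratio.  A
        degenerate interval (a == b) pins the CDR.  Samples must lie in
        (0, 1).  The default U(0.3, 0.9) straddles the 0.6 decision
        threshold symmetrically, giving balanced labels.
    axis_ratio_range
        Interval for the minor/major semi-axis ratio of the disc ellipse
        (1.0 = circle).
    cup_vertical_offset
        Cup-center offset, as a fraction of the free vertical rim space,
        mimicking vertical rim thinning.  0 keeps the cup concentric.
    vessel_count
        Number of dark vessel arcs radiating through the disc.
    noise_sd
        Standard deviation of additive Gaussian pixel noise.
    background_intensity
        Brightness multiplier of the retinal background.
    seed
        Default seed for :func:`generate_dataset` when none is passed.
    """

    image_size: int = 224
    od_radius_range: tuple[float, float] | None = None
    cdr_range: tuple[float, float] = (0.3, 0.9)
    axis_ratio_range: tuple[float, float] = (0.75, 1.0)
    cup_vertical_offset: float = 0.0
    vessel_count: int = 4
    noise_sd: float = 0.02
    background_intensity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.od_radius_range is None:
            object.__setattr__(
                self, "od_radius_range",
                (25.0 * self.image_size / 224, 50.0 * self.image_size / 224),
            )
        lo, hi = self.od_radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid od_radius_range {self.od_radius_range}")
        # margin of 2 px keeps the tight box strictly inside the frame
        if hi > self.image_size / 2 - 2:
            raise ValueError(
                f"disc radius up to {hi} px cannot fit a {self.image_size} px image"
            )
        clo, chi = self.cdr_range
        if not 0 < clo <= chi < 1:
            raise ValueError(f"cdr_range must lie within (0, 1), got {self.cdr_range}")
        alo, ahi = self.axis_ratio_range
        if not 0 < alo <= ahi <= 1:
            raise ValueError(f"axis_ratio_range must lie within (0, 1], got {self.axis_ratio_range}")
        if not 0 <= self.cup_vertical_offset <= 1:
            raise ValueError("cup_vertical_offset must be in [0, 1]")


@dataclass(frozen=True)
class FundusSample:
    """One rendered image with its exact ground truth."""

    image: np.ndarray  # H x W x 3, float in [0, 1]
    od_box: BoundingBox
    oc_box: BoundingBox
    true_cdr: float
    label: int  # 1 iff true_cdr >= 0.6
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        ob, cb = self.od_box, self.oc_box
        h, w = self.image.shape[:2]
        if not (0 <= ob.x_min and ob.x_max <= w and 0 <= ob.y_min and ob.y_max <= h):
            raise ValueError("od_box extends outside the image")
        if not (
            ob.x_min <= cb.x_min and cb.x_max <= ob.x_max
            and ob.y_min <= cb.y_min and cb.y_max <= ob.y_max
        ):
            raise ValueError("oc_box must lie inside od_box")


def _ellipse_box(cy: float, cx: float, b: float, a: float) -> BoundingBox:
    """Analytic tight bounds of an axis-aligned ellipse (a, b = x, y semi-axes)."""
    return BoundingBox(cx - a, cy - b, cx + a, cy + b)


def _draw_vessels(img: np.ndarray, cy: float, cx: float, count: int, rng: np.random.Generator) -> None:
    size = img.shape[0]
    for _ in range(count):
        theta = rng.uniform(0, 2 * np.pi)
        # endpoint on the frame boundary in direction theta, control point bent sideways
        r_end = size  # overshoot; coordinates are clipped below
        ey = cy + r_end * np.sin(theta)
        ex = cx + r_end * np.cos(theta)
        bend = rng.uniform(-0.4, 0.4) * size / 2
        my = (cy + ey) / 2 - bend * np.cos(theta)
        mx = (cx + ex) / 2 + bend * np.sin(theta)
        pts = np.array([[cy, cx], [my, mx], [ey, ex]])
        pts = np.clip(pts, 0, size - 1)
        rr, cc = bezier_curve(
            int(pts[0, 0]), int(pts[0, 1]), int(pts[1, 0]), int(pts[1, 1]),
            int(pts[2, 0]), int(pts[2, 1]), weight=1.0, shape=img.shape[:2],
        )
        # thicken to ~3 px by stamping a cross around each curve pixel
        for dy, dx in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
            r2 = np.clip(rr + dy, 0, size - 1)
            c2 = np.clip(cc + dx, 0, size - 1)
            img[r2, c2] = _VESSEL_COLOR


def generate_sample(config: SyntheticConfig, rng: np.random.Generator) -> FundusSample:
    """Render one annotated fundus-like image.

    Boxes are the analytic tight axis-aligned bounds of the rendered
    ellipses, so the box-derived semi-major CDR equals ``true_cdr`` exactly.
    """
    size = config.image_size
    shape = (size, size)

    # --- sample geometry -------------------------------------------------
    r_major = rng.uniform(*config.od_radius_range)
    q = rng.uniform(*config.axis_ratio_range)
    # elongation axis: vertical half the time (typical of real discs)
    if rng.random() < 0.5:
        a_od, b_od = r_major * q, r_major  # (horizontal, vertical) semi-axes
    else:
        a_od, b_od = r_major, r_major * q
    margin = 2.0
    cx = rng.uniform(a_od + margin, size - a_od - margin)
    cy = rng.uniform(b_od + margin, size - b_od - margin)
    cdr = rng.uniform(*config.cdr_range)
    a_oc, b_oc = cdr * a_od, cdr * b_od
    oc_cy = cy + config.cup_vertical_offset * (b_od - b_oc)

    # --- render ----------------------------------------------------------
    yy, xx = np.mgrid[0:size, 0:size]
    d = np.hypot(yy - size / 2, xx - size / 2) / (size / 2 * np.sqrt(2))
    vignette = config.background_intensity * (1.0 - 0.45 * d)
    img = vignette[..., None] * _BG_COLOR

    od_rr, od_cc = ellipse(cy, cx, b_od, a_od, shape=shape)
    img[od_rr, od_cc] = _DISC_COLOR
    oc_rr, oc_cc = ellipse(oc_cy, cx, b_oc, a_oc, shape=shape)
    img[oc_rr, oc_cc] = _CUP_COLOR
    _draw_vessels(img, cy, cx, config.vessel_count, rng)

    img = img + rng.normal(0.0, config.noise_sd, img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    label = 1 if cdr >= DEFAULT_THRESHOLD else 0
    od_box = _ellipse_box(cy, cx, b_od, a_od)
    oc_box = _ellipse_box(oc_cy, cx, b_oc, a_oc)
    # guard against float round-off at full vertical offset
    oc_box = BoundingBox(
        max(oc_box.x_min, od_box.x_min), max(oc_box.y_min, od_box.y_min),
        min(oc_box.x_max, od_box.x_max), min(oc_box.y_max, od_box.y_max),
    )
    return FundusSample(
        image=img,
        od_box=od_box,
        oc_box=oc_box,
        true_cdr=float(cdr),
        label=label,
    )


def generate_dataset(
    config: SyntheticConfig,
    n: int,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> list[FundusSample]:
    """Generate ``n`` samples; optionally write images + annotations to disk.

    Deterministic given ``(config, seed)``.  When ``out_dir`` is given the
    function writes one PNG per sample, an ``annotations.csv`` in the
    package's CSV dialect (one OD and one OC row per image), and a
    ``manifest.json`` recording the config, seed, and per-sample true CDR
    and label.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        s = generate_sample(config, rng)
        samples.append(dataclasses.replace(s, sample_id=f"sample_{i:04d}"))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        annotations = {}
        manifest_samples = []
        for s in samples:
            fname = f"{s.sample_id}.png"
            iio.imwrite(out / fname, (s.image * 255).round().astype(np.uint8))
            annotations[fname] = {"OD": s.od_box, "OC": s.oc_box}
            manifest_samples.append(
                {"image": fname, "true_cdr": s.true_cdr, "label": s.label}
            )
        write_annotations_csv(annotations, out / "annotations.csv")
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": seed,
            "n": n,
            "samples": manifest_samples,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return samples
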