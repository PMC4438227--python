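"""Rendering of the six-shape stimulus set.

The behavioral and electrophysiological experiments use six black-and-white
shapes (a square, a diamond in a square, a triangle, the letter lambda, the
letter H and a plus sign) shown on a black background.  The shapes are drawn
as outline strokes; the free parameter of each glyph is its stroke width,
which is tuned so that every shape has the same number of white pixels
(equal luminance).  Bounding-box widths span 23-33 degrees of visual angle
with a mean of 27.3 degrees.

The display geometry is a 1280 x 768 px screen subtending 102 x 68 degrees,
i.e. 1280/102 ~ 12.549 px/deg.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

#: Screen resolution over field of view: 1280 px across 102 deg.
PX_PER_DEG: float = 1280.0 / 102.0

#: Default canvas (full screen), rows x columns.
CANVAS_HEIGHT: int = 768
CANVAS_WIDTH: int = 1280

#: Canonical glyph order used throughout the analysis.
GLYPH_IDS: tuple[str, ...] = (
    "square",
    "diamond_in_square",
    "triangle",
    "lambda",
    "letter_H",
    "plus",
)

#: Default per-shape bounding-box widths (degrees).  Only the mean (27.3 deg)
#: and the range (23-33 deg) are constrained; the compact glyphs (square,
#: diamond) get the smaller boxes.  Sum = 163.8 -> mean exactly 27.3.
DEFAULT_WIDTHS_DEG: dict[str, float] = {
    "square": 23.0,
    "diamond_in_square": 24.0,
    "triangle": 26.0,
    "lambda": 29.8,
    "letter_H": 33.0,
    "plus": 28.0,
}

# Outline skeletons in a unit box, (x, y) with y pointing down.  Each glyph is
# a list of line segments; the rendered stroke is the set of pixels within
# stroke_width/2 of any segment.
_UNIT_SEGMENTS: dict[str, list[tuple[tuple[float, float], tuple[float, float]]]] = {
    "square": [
        ((0, 0), (1, 0)),
        ((1, 0), (1, 1)),
        ((1, 1), (0, 1)),
        ((0, 1), (0, 0)),
    ],
    "diamond_in_square": [
        ((0, 0), (1, 0)),
        ((1, 0), (1, 1)),
        ((1, 1), (0, 1)),
        ((0, 1), (0, 0)),
        ((0.5, 0), (1, 0.5)),
        ((1, 0.5), (0.5, 1)),
        ((0.5, 1), (0, 0.5)),
        ((0, 0.5), (0.5, 0)),
    ],
    "triangle": [
        ((0.5, 0), (1, 1)),
        ((1, 1), (0, 1)),
        ((0, 1), (0.5, 0)),
    ],
    "lambda": [
        ((0.25, 0), (0.9, 1)),
        ((0.51, 0.4), (0.1, 1)),
    ],
    "letter_H": [
        ((0, 0), (0, 1)),
        ((1, 0), (1, 1)),
        ((0, 0.5), (1, 0.5)),
    ],
    "plus": [
        ((0, 0.5), (1, 0.5)),
        ((0.5, 0), (0.5, 1)),
    ],
}


def _normalize_segments() -> None:
    # rescale every skeleton to span exactly [0, 1] in x and y, so the
    # target bounding box is met regardless of how the glyph was sketched
    for glyph, segs in _UNIT_SEGMENTS.items():
        pts = np.array([p for seg in segs for p in seg], dtype=float)
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        _UNIT_SEGMENTS[glyph] = [
            (tuple((np.asarray(a) - lo) / span), tuple((np.asarray(b) - lo) / span))
            for a, b in segs
        ]


_normalize_segments()


@dataclass(frozen=True)
class ShapeSpec:
    """Parameters of one glyph: identity, angular size, stroke width."""

    glyph_id: str
    target_bbox_width: float  # degrees of visual angle
    stroke_width: float = 35.0  # px; the luminance-equalization knob
    aspect: float = 1.0  # bbox height / bbox width

    def __post_init__(self) -> None:
        if self.glyph_id not in _UNIT_SEGMENTS:
            raise ValueError(f"unknown glyph_id {self.glyph_id!r}")
        if self.stroke_width <= 0:
            raise ValueError("stroke_width must be positive")


@dataclass
class ShapeImage:
    """A binary raster (1 = white foreground) with its angular calibration."""

    glyph_id: str
    raster: np.ndarray  # 2-D uint8 array with entries in {0, 1}
    px_per_deg: float

    def __post_init__(self) -> None:
        r = np.asarray(self.raster)
        if r.ndim != 2:
            raise ValueError("raster must be 2-D")
        if not np.isin(r, (0, 1)).all():
            raise ValueError("raster entries must be 0 or 1")
        if not r.any():
            raise ValueError(f"glyph {self.glyph_id!r} has no foreground pixels")
        self.raster = r.astype(np.uint8)

    @property
    def white_count(self) -> int:
        return int(self.raster.sum())


@dataclass
class StimulusSet:
    """Six equal-luminance shapes plus the canonical 15-pair index."""

    shapes: list[ShapeImage]
    specs: list[ShapeSpec]
    pair_index: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.shapes) != 6:
            raise ValueError("a stimulus set holds exactly 6 shapes")
        if not self.pair_index:
            self.pair_index = pair_index(6)

    @property
    def glyph_ids(self) -> list[str]:
        return [s.glyph_id for s in self.shapes]

    @property
    def px_per_deg(self) -> float:
        return self.shapes[0].px_per_deg


def pair_index(n: int = 6) -> list[tuple[int, int]]:
    """All unordered pairs (i, j), j > i, in lexicographic order.

    For six shapes this is the canonical 15-pair ordering shared by every
    dissimilarity / decoding vector in the analysis.
    """
    return [(i, j) for i, j in itertools.combinations(range(n), 2)]


#: The four movement-axis orders used during stimulus presentation
#: (horizontal, vertical and the two diagonals, in four fixed orders).
AXIS_ORDERS: tuple[str, ...] = ("HVDd", "VDdH", "DdHV", "dHVD")


def stimulus_conditions() -> list[tuple[str, str]]:
    """Cross of 6 shapes x 4 movement-axis orders = 24 presentation conditions."""
    return list(itertools.product(GLYPH_IDS, AXIS_ORDERS))


def _segment_distance(px: np.ndarray, py: np.ndarray,
                      p: tuple[float, float], q: tuple[float, float]) -> np.ndarray:
    """Euclidean distance from grid points to the segment p-q."""
    vx, vy = q[0] - p[0], q[1] - p[1]
    dx, dy = px - p[0], py - p[1]
    denom = vx * vx + vy * vy
    if denom == 0:
        return np.hypot(dx, dy)
    t = np.clip((dx * vx + dy * vy) / denom, 0.0, 1.0)
    return np.hypot(dx - t * vx, dy - t * vy)


def _distance_field(spec: ShapeSpec, canvas_height: int, canvas_width: int,
                    px_per_deg: float, stroke: float):
    """Distance from each pixel (in a region around the glyph box) to the
    glyph skeleton, with the skeleton inset by half the stroke width.

    The inset makes the white-pixel bounding box match ``target_bbox_width``
    to about a pixel regardless of stroke width: stroke caps extend exactly
    to the un-inset box edges.  Returns (distances, (r0, r1, c0, c1)).
    """
    if px_per_deg <= 0:
        raise ValueError("px_per_deg must be positive")
    w_px = spec.target_bbox_width * px_per_deg
    h_px = w_px * spec.aspect
    if w_px > canvas_width or h_px > canvas_height:
        raise ValueError(
            f"glyph {spec.glyph_id!r} needs a {h_px:.0f}x{w_px:.0f} px canvas, "
            f"got {canvas_height}x{canvas_width}"
        )
    s = min(stroke, 0.9 * min(w_px, h_px))
    x0 = (canvas_width - 1) / 2.0 - w_px / 2.0
    y0 = (canvas_height - 1) / 2.0 - h_px / 2.0
    ix0, iy0 = x0 + s / 2.0, y0 + s / 2.0
    iw, ih = max(w_px - s, 1e-6), max(h_px - s, 1e-6)

    c0 = max(int(np.floor(x0)) - 1, 0)
    c1 = min(int(np.ceil(x0 + w_px)) + 2, canvas_width)
    r0 = max(int(np.floor(y0)) - 1, 0)
    r1 = min(int(np.ceil(y0 + h_px)) + 2, canvas_height)
    cols = np.arange(c0, c1, dtype=float)
    rows = np.arange(r0, r1, dtype=float)
    px, py = np.meshgrid(cols, rows)

    dist = np.full(px.shape, np.inf)
    for (ax, ay), (bx, by) in _UNIT_SEGMENTS[spec.glyph_id]:
        p = (ix0 + ax * iw, iy0 + ay * ih)
        q = (ix0 + bx * iw, iy0 + by * ih)
        dist = np.minimum(dist, _segment_distance(px, py, p, q))
    return dist, (r0, r1, c0, c1)


def _dither(region_shape: tuple[int, int], r0: int, c0: int) -> np.ndarray:
    """Deterministic sub-millipixel jitter that breaks distance ties.

    Axis-aligned strokes put whole pixel rows at exactly the same distance
    from the skeleton; the jitter lets luminance equalization place a
    fractional stroke edge without visible structure.
    """
    rows = np.arange(r0, r0 + region_shape[0])[:, None]
    cols = np.arange(c0, c0 + region_shape[1])[None, :]
    h = (rows * 2654435761 ^ cols * 40503) % 4096
    return h.astype(float) / 4096.0 * 1e-3


def render_shape(spec: ShapeSpec,
                 canvas_height: int = CANVAS_HEIGHT,
                 canvas_width: int = CANVAS_WIDTH,
                 px_per_deg: float = PX_PER_DEG) -> ShapeImage:
    """Render one glyph, centered, on an all-black canvas.

    A pixel is white when its distance to the (inset) glyph skeleton is at
    most half the stroke width.
    """
    dist, (r0, r1, c0, c1) = _distance_field(
        spec, canvas_height, canvas_width, px_per_deg, spec.stroke_width)
    raster = np.zeros((canvas_height, canvas_width), dtype=np.uint8)
    raster[r0:r1, c0:c1] = dist <= spec.stroke_width / 2.0
    return ShapeImage(spec.glyph_id, raster, px_per_deg)


def bbox_width_deg(image: ShapeImage) -> float:
    """Width, in degrees, of the minimal rectangle containing all white pixels."""
    cols = np.flatnonzero(image.raster.any(axis=0))
    if cols.size == 0:
        raise ValueError("image has no foreground pixels")
    return (cols[-1] - cols[0] + 1) / image.px_per_deg


def default_specs(mean_width_deg: float = 27.3) -> list[ShapeSpec]:
    """The six default glyph specs, rescaled so their mean width is as given."""
    scale = mean_width_deg / 27.3
    return [ShapeSpec(g, DEFAULT_WIDTHS_DEG[g] * scale) for g in GLYPH_IDS]


def build_stimulus_set(specs: list[ShapeSpec] | None = None,
                       canvas_height: int = CANVAS_HEIGHT,
                       canvas_width: int = CANVAS_WIDTH,
                       px_per_deg: float = PX_PER_DEG,
                       luminance_tol: float = 0.01,
                       max_iter: int = 60) -> StimulusSet:
    """Render all six glyphs and equalize their white-pixel counts.

    The target count is the median of the initial renders.  For each glyph
    the stroke width is iterated to a fixed point against its distance
    field, and the raster lights exactly the ``target`` pixels closest to
    the skeleton — a sub-pixel stroke edge, so every glyph ends with an
    identical white-pixel count (far inside any sensible tolerance).
    """
    if specs is None:
        specs = default_specs()
    ids = [s.glyph_id for s in specs]
    if len(specs) != 6 or len(set(ids)) != 6:
        raise ValueError("need exactly 6 distinct glyph specs")

    initial = [render_shape(sp, canvas_height, canvas_width, px_per_deg)
               for sp in specs]
    target = int(np.median([im.white_count for im in initial]))

    final_specs: list[ShapeSpec] = []
    final_images: list[ShapeImage] = []
    for sp in specs:
        stroke = sp.stroke_width
        dist = region = None
        for _ in range(max_iter):
            dist, region = _distance_field(sp, canvas_height, canvas_width,
                                           px_per_deg, stroke)
            if target > dist.size:
                raise RuntimeError(
                    f"luminance equalization failed for {sp.glyph_id!r}: "
                    f"target {target} exceeds the {dist.size}-px glyph region")
            jittered = dist + _dither(dist.shape, region[0], region[2])
            kth = np.partition(jittered.ravel(), target - 1)[target - 1]
            new_stroke = 2.0 * kth
            if abs(new_stroke - stroke) < 1e-6:
                stroke = new_stroke
                break
            stroke = new_stroke
        jittered = dist + _dither(dist.shape, region[0], region[2])
        flat_idx = np.argpartition(jittered.ravel(), target - 1)[:target]
        lit = np.zeros(dist.shape, dtype=bool)
        lit.ravel()[flat_idx] = True
        raster = np.zeros((canvas_height, canvas_width), dtype=np.uint8)
        r0, r1, c0, c1 = region
        raster[r0:r1, c0:c1] = lit
        image = ShapeImage(sp.glyph_id, raster, px_per_deg)
        if abs(image.white_count - target) > luminance_tol * target:
            raise RuntimeError(
                f"luminance equalization failed for {sp.glyph_id!r}: "
                f"count {image.white_count} vs target {target}")
        final_specs.append(ShapeSpec(sp.glyph_id, sp.target_bbox_width,
                                     stroke, sp.aspect))
        final_images.append(image)

    return StimulusSet(final_images, final_specs)


# ---------------------------------------------------------------------------
# PNG / manifest I/O

def save_set(stim: StimulusSet, out_dir: str | Path) -> Path:
    """Write 8-bit grayscale PNGs (foreground = 255) plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"px_per_deg": stim.px_per_deg, "shapes": []}
    for im, sp in zip(stim.shapes, stim.specs):
        fname = f"{im.glyph_id}.png"
        Image.fromarray(im.raster * np.uint8(255), mode="L").save(out / fname)
        manifest["shapes"].append({
            "glyph_id": im.glyph_id,
            "file": fname,
            "white_count": im.white_count,
            "target_bbox_width_deg": sp.target_bbox_width,
            "stroke_width_px": sp.stroke_width,
        })
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out / "manifest.json"


def load_set(in_dir: str | Path) -> StimulusSet:
    """Read a stimulus set written by :func:`save_set`."""
    in_dir = Path(in_dir)
    manifest = json.loads((in_dir / "manifest.json").read_text())
    shapes, specs = [], []
    for entry in manifest["shapes"]:
        arr = np.asarray(Image.open(in_dir / entry["file"]).convert("L"))
        shapes.append(ShapeImage(entry["glyph_id"], (arr > 127).astype(np.uint8),
                                 manifest["px_per_deg"]))
        specs.append(ShapeSpec(entry["glyph_id"], entry["target_bbox_width_deg"],
                               entry["stroke_width_px"]))
    return StimulusSet(shapes, specs)
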